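"""Place a measured airway resistance in its reference distribution.

A 250 g female Sprague Dawley rat ventilated at PEEP 2 cmH2O has a
measured Raw of 60 cmH2O.s/l.  Is that normal for her size, sex, strain
and ventilator setting?
"""
import pulmoref as pr

models = pr.default_models()
raw_model = models[pr.Outcome.RAW]

cov = pr.CovariateSet(mass_g=250, strain="sprague_dawley", sex="female", peep_cmH2O=2)

result = raw_model.z_score(cov, observed=60.0)
lo, hi = raw_model.normal_range(cov, central_mass=0.90)

print(f"predicted median Raw : {result.predicted_median:.1f} cmH2O.s/l")
print(f"normal range (90%)   : {lo:.1f} - {hi:.1f} cmH2O.s/l")
print(f"observed 60.0        : z = {result.z:+.2f}, percentile {result.percentile:.1f}")
print(f"classification       : {result.classification}")

# A z of about +1 means the measurement sits one reference standard
# deviation above the expected median on the log scale -- elevated but
# inside the central 90% of healthy animals.
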