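"""Classify one sample against the packaged synthetic reference cohort.

Single-sample mode appends the query to a reference feature table,
rescales, refits the mixture, and reports the query's call — useful when a
run contains too few samples for unsupervised clustering.
"""

from sexkaryo import SampleFeatures, infer_single_sample
from sexkaryo.cli import packaged_reference

reference = packaged_reference()
query = SampleFeatures(
    sample_id="query01",
    XH=0.001, Xmap=0.0182, Ymap=0.00065,
    XYratio=0.0182 / 0.00065, SRY_dep=28.0,
)
call = infer_single_sample(query, reference, seed=3)

print(f"reference cohort:  {len(reference)} samples "
      f"({', '.join(reference.selected_features)})")
print(f"{call.sample_id}: sex={call.sex}  "
      f"uncertainty={call.uncertainty:.2e}  outlier={call.outlier}")

# The query has male-typical values for all five features (near-zero X
# heterozygosity, Y coverage, SRY depth ≈ 28x), so it lands deep inside
# the male component with near-zero uncertainty.
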