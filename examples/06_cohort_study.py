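"""A full synthetic two-group study: simulate -> quantify -> compare.

Patients carry nasal-predominant inner-layer thinning and a smaller
attenuation increase; the pipeline quantifies every subject, calibrates
beta, and produces group-comparison, correlation and ROC tables.
"""

from octquant.phantom import CohortSpec, PhantomSpec
from octquant.pipeline import RunConfig, render_report, run_pipeline

base = PhantomSpec(grid_shape=(48, 24, 176), voxel_size=(125.0, 250.0, 2.3),
                   ilm_offset_um=40.0)
config = RunConfig(
    cohort=CohortSpec(n_per_group=15, base=base, seed=20),
    use_truth_surfaces=True,   # skip segmentation: quantify on true surfaces
)
bundle = run_pipeline(config, outdir="scratch/example_cohort")

thick = bundle.tables["thickness_comparison"]
print(thick[thick.layer == "mRNFL"][
    ["region", "patient", "control", "test", "p"]].to_string(index=False))
print("\nNasal (SN/IN) mRNFL rows should carry the small p-values: that is "
      "the designed effect.")

roc = bundle.tables["roc"]
sel = roc[(roc.layer == "mRNFL") & (roc.region == "Average")]
print(sel[["measure", "auc_se", "p"]].to_string(index=False))
print("\nThickness discriminates better than the attenuation index, "
      "mirroring the designed (and clinically reported) pattern.")
print("\nFull report written to scratch/example_cohort/report.md")
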