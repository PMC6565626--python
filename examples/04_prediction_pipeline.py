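"""Full pipeline: simulate -> preprocess -> density -> latent -> predict.

Simulates a 7-versus-23 cohort with both linguistic effects planted, writes
it to disk in the pipeline's file formats, runs the complete analysis, and
prints the fitted logistic models: density-only, concept-only, and the
combined two-predictor model with its Wald statistics.
"""

import tempfile
from pathlib import Path

import semdens as sd
from semdens.pipeline import RunConfig
from semdens.synthetic import (FixtureSpec, make_baseline_corpus, make_cohort,
                               make_embedding_space, write_baseline_corpus,
                               write_cohort)

workdir = Path(tempfile.mkdtemp())
spec = FixtureSpec(seed=3)
space = make_embedding_space(spec)
write_cohort(make_cohort(spec, space), workdir)
space.save(workdir / "embeddings.txt")
space.save_frequency(workdir / "frequencies.tsv")
write_baseline_corpus(make_baseline_corpus(spec, space, 30),
                      workdir / "baseline.txt")

config = RunConfig(
    transcripts=str(workdir / "transcripts.tsv"),
    embeddings=str(workdir / "embeddings.txt"),
    frequency=str(workdir / "frequencies.tsv"),
    labels=str(workdir / "labels.tsv"),
    baseline=str(workdir / "baseline.txt"),
    outdir=str(workdir / "run"),
    seed=3,
    unpacking=sd.UnpackingConfig.desk_scale(),
)
report = sd.run_full_pipeline(config)

print(f"run {report['config_hash']} (seed {report['seed']}), "
      f"tagger: {report['tagger']}")
print(f"concept cluster: "
      f"{', '.join(k.split('_', 1)[1] for k in report['concept_members'])}\n")
for name, entry in report["models"].items():
    model, metrics = entry["model"], entry["metrics"]
    coef = ", ".join(f"{n}={model.coef(n):+.2f}" for n in model.predictor_names)
    wald = ", ".join(f"chi2({n})={entry['wald'][n][0]:.2f} p={entry['wald'][n][1]:.3f}"
                     for n in model.predictor_names)
    print(f"{name:9s} accuracy={metrics.accuracy:.2f} f1={metrics.f1 and round(metrics.f1, 2)}"
          f"  [{coef}]")
    print(f"          {wald}"
          + (f"  boundary={entry['boundary']:.3f}" if entry.get("boundary") else ""))
print("\nBoth predictors contribute; the combined model matches or beats")
print("each single-predictor model on training accuracy.")
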