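"""End-to-end orchestration: preprocess -> embeddings -> density -> latent
content -> prediction, as reproducible runs.

Stages communicate through UTF-8 delimited tables in the run's output
directory; every table carries a header comment with the config hash and
seed so a ``verify`` pass can detect mixed-up run directories.  The same
steps are available in-process through :func:`run_full_pipeline` /
:func:`run_shuffle_control` for library use.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import latent as lc
from . import predict as pe
from .density import UnpackingConfig, compose_sentence_vector, participant_density
from .embeddings import EmbeddingSpace, probe_vocabulary
from .errors import ConfigurationError, SkipSentence
from .preprocess import (ContentSentence, pos_shuffle_cohort,
                         preprocess_utterances, read_transcripts)
from .tagger import RuleBasedTagger, sentence_split, word_tokenize

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    transcripts: str
    embeddings: str
    outdir: str
    labels: str | None = None
    baseline: str | None = None
    holdout_transcripts: str | None = None
    holdout_labels: str | None = None
    frequency: str | None = None
    coverage: float = 0.95
    topk: int = 50
    k_min: int = 2
    k_max: int = 10
    threshold: float = 0.5
    max_sentence_len: int = 60
    shuffle_scope: str = "participant"
    seed: int = 0
    unpacking: UnpackingConfig = field(default_factory=UnpackingConfig)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
        unpack_raw = raw.pop("unpacking", {})
        if "candidate_keys" in unpack_raw and unpack_raw["candidate_keys"] is not None:
            unpack_raw["candidate_keys"] = tuple(unpack_raw["candidate_keys"])
        return cls(unpacking=UnpackingConfig(**unpack_raw), **raw)

    def config_hash(self) -> str:
        """Hash of the analysis configuration (the output location is not
        part of the analysis identity)."""
        payload = asdict(self)
        payload.pop("outdir", None)
        payload = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _stamp(path: Path, df: pd.DataFrame, config: RunConfig) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# config_hash: {config.config_hash()}\n")
        fh.write(f"# seed: {config.seed}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_stamped(path: str | Path) -> tuple[pd.DataFrame, dict]:
    meta = {}
    with open(path, encoding="utf-8") as fh:
        pos = fh.tell()
        while True:
            line = fh.readline()
            if line.startswith("# "):
                key, _, val = line[2:].partition(":")
                meta[key.strip()] = val.strip()
                pos = fh.tell()
            else:
                fh.seek(pos)
                break
        df = pd.read_csv(fh, sep="\t")
    return df, meta


def _load_inputs(config: RunConfig):
    for name in ("transcripts", "embeddings"):
        p = getattr(config, name)
        if not Path(p).exists():
            raise ConfigurationError(f"stage '{name}': path {p!r} does not exist")
    freq = (EmbeddingSpace.load_frequency(config.frequency)
            if config.frequency else None)
    space = EmbeddingSpace.load(config.embeddings, frequency=freq)
    utterances = read_transcripts(config.transcripts)
    transcripts = preprocess_utterances(
        utterances, role="participant", max_len=config.max_sentence_len)
    labels = None
    if config.labels:
        ldf = pd.read_csv(config.labels, sep="\t", dtype={"participant_id": str})
        labels = dict(zip(ldf.participant_id, ldf.label.astype(int)))
    return space, utterances, transcripts, labels


def _density_table(transcripts: dict[str, list[ContentSentence]],
                   space: EmbeddingSpace, config: RunConfig) -> pd.DataFrame:
    rows = []
    for pid in sorted(transcripts):
        for idx, sent in enumerate(transcripts[pid]):
            try:
                from .density import unpack_sentence
                res = unpack_sentence(sent, space, config.unpacking)
            except SkipSentence as exc:
                logger.info("density: skipped %s sentence %d (%s)", pid, idx, exc)
                continue
            rows.append({"participant_id": pid, "sentence_idx": idx,
                         "n_content": sent.n_content, "m": res.m,
                         "density": res.density, "cost": res.final_cost,
                         "repartitioned": res.repartitioned})
    return pd.DataFrame(rows)


def _mean_density_table(sent_df: pd.DataFrame) -> pd.DataFrame:
    agg = sent_df.groupby("participant_id").agg(
        mean_density=("density", "mean"),
        sentence_count=("density", "size")).reset_index()
    return agg


def _sentence_vectors(transcripts: dict[str, list[ContentSentence]],
                      space: EmbeddingSpace):
    out = {}
    for pid, sents in transcripts.items():
        vecs = []
        for s in sents:
            try:
                vecs.append(compose_sentence_vector(s, space))
            except SkipSentence:
                continue
        if vecs:
            out[pid] = vecs
    return out


def _baseline_profiles(config: RunConfig, probes, space: EmbeddingSpace):
    """One profile per baseline document (line-delimited)."""
    tagger = RuleBasedTagger()
    profiles = []
    for i, line in enumerate(
            Path(config.baseline).read_text(encoding="utf-8").splitlines()):
        if not line.strip():
            continue
        sents = []
        for raw in sentence_split(line):
            tokens = tagger.tag_tokens(word_tokenize(raw))
            keys = tuple(f"{t}_{l}" for _, t, l in tokens
                         if t in ("NN", "VB", "JJ", "RB"))
            if keys:
                try:
                    sents.append(compose_sentence_vector(
                        ContentSentence(keys, f"base{i}"), space))
                except SkipSentence:
                    continue
        if sents:
            profiles.append(lc.probe_profile(probes, sents, space, f"base{i}"))
    return profiles


def run_latent_stage(config: RunConfig, space: EmbeddingSpace,
                     transcripts, labels) -> dict:
    """Probe contrast -> clustering -> concept predictor per participant."""
    if config.baseline is None:
        raise ConfigurationError("stage 'latent': baseline corpus path required")
    probes = probe_vocabulary(space, config.coverage)
    vectors = _sentence_vectors(transcripts, space)
    profiles = {pid: lc.probe_profile(probes, vecs, space, pid)
                for pid, vecs in vectors.items()}
    pos_ids = sorted(p for p in profiles if labels and labels.get(p) == 1)
    group_ids = pos_ids if pos_ids else sorted(profiles)
    group = lc.group_profile([profiles[p] for p in group_ids], "group")
    base_profiles = _baseline_profiles(config, probes, space)
    baseline = lc.group_profile(base_profiles, "baseline")
    contrast = lc.contrast_weight(group, baseline)
    top = lc.top_probes(contrast, config.topk)
    solution = lc.cluster_probes(top, space,
                                 range(config.k_min, config.k_max + 1),
                                 seed=config.seed)
    # concept cluster: the one with the highest mean contrast weight
    by_cluster: dict[int, list[str]] = {}
    for p, label in solution.labels.items():
        by_cluster.setdefault(label, []).append(p)
    def _mean_weight(members):
        return np.mean([contrast.weighted_scores[p] for p in members])
    concept_members = max(by_cluster.values(), key=_mean_weight)
    concept = lc.concept_vector(concept_members, space)
    predictor = {pid: lc.concept_predictor(concept, vecs)
                 for pid, vecs in vectors.items()}
    return {"contrast": contrast, "top_probes": top, "clusters": solution,
            "concept_members": sorted(concept.member_keys),
            "concept": concept, "predictor": predictor}


def _fit_models(feature_df: pd.DataFrame, labels: dict[str, int]) -> dict:
    df = feature_df.set_index("participant_id")
    y = np.array([labels[p] for p in df.index])
    models = {}
    specs = {"density": ["mean_density"], "concept": ["concept_score"],
             "combined": ["mean_density", "concept_score"]}
    for name, cols in specs.items():
        if not all(c in df.columns for c in cols):
            continue
        model = pe.fit_logistic(df[cols], y)
        metrics = pe.evaluate_transfer(model, df[cols], y)
        wald = {c: pe.wald_chi2(model, c) for c in cols}
        entry = {"model": model, "metrics": metrics, "wald": wald}
        if len(cols) == 1:
            try:
                entry["boundary"] = pe.decision_boundary(model)
            except Exception as exc:  # zero slope
                entry["boundary"] = None
                logger.info("no decision boundary for %s: %s", name, exc)
        models[name] = entry
    return models


def run_full_pipeline(config: RunConfig) -> dict:
    """Execute all stages and write stamped tables to the output directory.

    Returns a report dict with per-participant features, fitted models,
    Wald tables, boundaries and metrics.  Any stage failure aborts with the
    stage name; tables written so far are preserved.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stage = "load"
    try:
        space, utterances, transcripts, labels = _load_inputs(config)
        stage = "density"
        sent_df = _density_table(transcripts, space, config)
        _stamp(outdir / "sentence_density.tsv", sent_df, config)
        mean_df = _mean_density_table(sent_df)
        _stamp(outdir / "participant_density.tsv", mean_df, config)
        features = mean_df[["participant_id", "mean_density"]].copy()
        report = {"config_hash": config.config_hash(), "seed": config.seed,
                  "tagger": RuleBasedTagger.name}
        stage = "latent"
        if config.baseline is not None:
            latent_out = run_latent_stage(config, space, transcripts, labels)
            pred = latent_out["predictor"]
            features["concept_score"] = features.participant_id.map(pred)
            contrast_df = pd.DataFrame({
                "probe": latent_out["contrast"].probes,
                "group_cosine": latent_out["contrast"].group_scores,
                "baseline_cosine": latent_out["contrast"].baseline_scores,
                "weighted": [latent_out["contrast"].weighted_scores[p]
                             for p in latent_out["contrast"].probes]})
            _stamp(outdir / "contrast.tsv", contrast_df, config)
            cluster_df = pd.DataFrame({
                "probe": list(latent_out["clusters"].labels),
                "cluster": list(latent_out["clusters"].labels.values())})
            _stamp(outdir / "clusters.tsv", cluster_df, config)
            report["concept_members"] = latent_out["concept_members"]
            report["n_clusters"] = latent_out["clusters"].k
            report["silhouette"] = latent_out["clusters"].silhouette
        _stamp(outdir / "features.tsv", features, config)
        stage = "predict"
        if labels is not None:
            models = _fit_models(features.dropna(axis=1), labels)
            report["models"] = models
            summary_rows = []
            for name, entry in models.items():
                m = entry["metrics"]
                summary_rows.append({
                    "model": name,
                    "accuracy": m.accuracy, "f1": m.f1,
                    "precision": m.precision, "recall": m.recall,
                    "specificity": m.specificity,
                    "boundary": entry.get("boundary"),
                    "separation": entry["model"].separation})
            _stamp(outdir / "model_summary.tsv", pd.DataFrame(summary_rows), config)
        report["features"] = features
        return report
    except Exception as exc:
        raise ConfigurationError(f"pipeline stage {stage!r} failed: {exc}") from exc


def run_shuffle_control(config: RunConfig, n_shuffles: int = 20) -> dict:
    """Refit the density model on POS-shuffled transcripts.

    Returns the original Wald statistic for mean density and its
    distribution across shuffles.
    """
    space, utterances, transcripts, labels = _load_inputs(config)
    if labels is None:
        raise ConfigurationError("shuffle control requires labels")

    def _wald_for(trs):
        sent_df = _density_table(trs, space, config)
        mean_df = _mean_density_table(sent_df)
        y = np.array([labels[p] for p in mean_df.participant_id])
        model = pe.fit_logistic(mean_df[["mean_density"]], y)
        return pe.wald_chi2(model, "mean_density")[0]

    original = _wald_for(transcripts)
    rng = np.random.default_rng(config.seed)
    shuffled_stats = []
    for _ in range(n_shuffles):
        trs = pos_shuffle_cohort(transcripts, int(rng.integers(2**31)),
                                 scope=config.shuffle_scope)
        shuffled_stats.append(_wald_for(trs))
    return {"original_wald": original, "shuffled_wald": shuffled_stats,
            "shuffle_median": float(np.median(shuffled_stats))}


def verify_run(outdir: str | Path) -> bool:
    """Check that all stamped tables in a run directory share one config
    hash; raises on mismatch, returns True otherwise."""
    hashes = {}
    for path in sorted(Path(outdir).glob("*.tsv")):
        _, meta = read_stamped(path)
        if "config_hash" in meta:
            hashes[path.name] = meta["config_hash"]
    if len(set(hashes.values())) > 1:
        raise ConfigurationError(f"mixed config hashes in run directory: {hashes}")
    return True
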