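"""Run configuration and the end-to-end pipeline.

A :class:`RunConfig` collects every tunable (paths, k-mer spec, candidate
window q, fold count, ensemble hyperparameters, negative-sampling ratio,
noise settings, seed) with documented defaults; it serializes to a flat
``key: value`` text file that re-parses to an equal config.
:func:`run_pipeline` executes extract -> select -> evaluate into a run
directory, stamping every artifact with the config hash and seed; a rerun
with an identical config reproduces identical JSON outputs.  One run seed
deterministically derives all stage seeds (logged, so any stage can be
re-run in isolation).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from ._seeds import derive_seed
from .core import EnsembleConfig, SelectionConfig, make_classifier, select_features
from .evaluation import crossvalidate
from .featurization import (
    AMINO_ACID,
    NUCLEOTIDE,
    FeatureSpec,
    InteractionMatrix,
    PairDataset,
    build_pair_dataset,
    featurize_sequences,
    read_fasta,
    read_pair_list,
    sample_negatives,
)

__all__ = ["RunConfig", "PipelineError", "run_pipeline"]

_log = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failure, tagged with the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")


@dataclass
class RunConfig:
    """All pipeline tunables; every field has a working default."""

    lnc_fasta: str = ""
    prot_fasta: str = ""
    pairs: str = ""
    features: str = ""  # precomputed feature table (alternative to FASTA inputs)
    out_dir: str = "rbfs_run"
    neg_ratio: float = 1.0
    seed: int = 0
    nucleotide_k: tuple[int, ...] = (1, 2, 3, 4)
    amino_acid_k: tuple[int, ...] = (1, 2)
    q: int = 10
    folds: int = 5
    n_estimators: int = 200
    max_depth: int = 6
    learning_rate: float = 0.1
    max_iterations: int = 100
    noise_groups: int = 5
    noise_distribution: str = "uniform-in-feature-range"

    def feature_spec(self) -> FeatureSpec:
        return FeatureSpec(tuple(self.nucleotide_k), tuple(self.amino_acid_k))

    def ensemble(self) -> EnsembleConfig:
        return EnsembleConfig(self.n_estimators, self.max_depth, self.learning_rate)

    def selection(self, seed: int) -> SelectionConfig:
        return SelectionConfig(
            q=self.q,
            k=self.folds,
            seed=seed,
            max_iterations=self.max_iterations,
            ensemble=self.ensemble(),
        )

    def to_text(self) -> str:
        lines = []
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if isinstance(v, tuple):
                v = ",".join(str(x) for x in v)
            lines.append(f"{f.name}: {v}")
        return "\n".join(lines) + "\n"

    @classmethod
    def from_text(cls, text: str) -> "RunConfig":
        types = {f.name: f for f in dataclasses.fields(cls)}
        kwargs = {}
        for lineno, line in enumerate(text.splitlines(), 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if ":" not in line:
                raise ValueError(f"config line {lineno}: expected 'key: value'")
            key, _, val = line.partition(":")
            key, val = key.strip(), val.strip()
            if key not in types:
                raise ValueError(f"config line {lineno}: unknown key {key!r}")
            ftype = types[key].type
            if ftype in ("int", int):
                kwargs[key] = int(val)
            elif ftype in ("float", float):
                kwargs[key] = float(val)
            elif "tuple" in str(ftype):
                kwargs[key] = tuple(int(x) for x in val.split(",") if x.strip())
            else:
                kwargs[key] = val
        return cls(**kwargs)

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        return cls.from_text(Path(path).read_text())

    def hash(self) -> str:
        """Hash of the scientific configuration (output location excluded)."""
        text = "\n".join(
            line
            for line in self.to_text().splitlines()
            if not line.startswith("out_dir:")
        )
        return hashlib.sha256(text.encode()).hexdigest()[:16]


def _extract(config: RunConfig, seed: int) -> PairDataset:
    if config.features:
        path = Path(config.features)
        if not path.exists():
            raise PipelineError("extract", f"feature table not found: {path}")
        return PairDataset.read_table(path)
    for name in ("lnc_fasta", "prot_fasta", "pairs"):
        path = getattr(config, name)
        if not path:
            raise PipelineError("extract", f"config field {name!r} is empty")
        if not Path(path).exists():
            raise PipelineError("extract", f"input file not found: {path}")
    spec = config.feature_spec()
    lncs = read_fasta(config.lnc_fasta, NUCLEOTIDE)
    prots = read_fasta(config.prot_fasta, AMINO_ACID)
    positives = read_pair_list(config.pairs)
    interactions = InteractionMatrix.from_pairs(
        positives, [r.id for r in lncs], [r.id for r in prots]
    )
    negatives = sample_negatives(interactions, config.neg_ratio, seed)
    lnc_feats, lnc_names = featurize_sequences(lncs, spec, prefix="lnc:")
    prot_feats, prot_names = featurize_sequences(prots, spec, prefix="prot:")
    return build_pair_dataset(
        lnc_feats, prot_feats, positives, negatives, lnc_names, prot_names
    )


def run_pipeline(config: RunConfig) -> Path:
    """Execute extract -> select -> evaluate; return the run directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_hash = config.hash()
    (out / "config.txt").write_text(config.to_text())

    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger = logging.getLogger("rbfs.pipeline")
    logger.setLevel(logging.INFO)
    logger.addHandler(handler)
    stamp = {"config_hash": cfg_hash, "seed": config.seed}
    try:
        seeds = {
            stage: derive_seed(config.seed, idx)
            for idx, stage in enumerate(("extract", "select", "evaluate"), start=10)
        }
        logger.info("config hash %s; run seed %d", cfg_hash, config.seed)
        for stage, s in seeds.items():
            logger.info("stage seed: %s -> %d", stage, s)

        logger.info("stage extract: building feature table")
        data = _extract(config, seeds["extract"])
        data.write_table(out / "features.tsv")
        logger.info(
            "stage extract: %d pairs x %d features (%d positive)",
            data.n_samples,
            data.n_features,
            int(data.labels.sum()),
        )

        logger.info("stage select: q=%d folds=%d", config.q, config.folds)
        try:
            result = select_features(
                data.X, data.labels, config.selection(seeds["select"])
            )
        except Exception as exc:
            raise PipelineError("select", str(exc)) from exc
        result.feature_names = data.feature_names
        payload = json.loads(result.to_json())
        payload.update(stamp)
        (out / "selection.json").write_text(json.dumps(payload, indent=2))
        logger.info("stage select: %d features selected", result.n_selected)

        logger.info("stage evaluate: %d-fold cross-validation", config.folds)
        try:
            report = crossvalidate(
                data.X,
                data.labels,
                result.selected,
                k=config.folds,
                seed=seeds["evaluate"],
                model_factory=lambda s: make_classifier(config.ensemble(), s),
            )
        except Exception as exc:
            raise PipelineError("evaluate", str(exc)) from exc
        (out / "metrics.json").write_text(report.to_json(**stamp))
        (out / "report.txt").write_text(report.to_text_table() + "\n")
        logger.info("stage evaluate: mean accuracy %.4f", report.mean["accuracy"])
        return out
    except PipelineError:
        (out / "INCOMPLETE").write_text("pipeline did not finish; see run.log\n")
        raise
    finally:
        logger.removeHandler(handler)
        handler.close()
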