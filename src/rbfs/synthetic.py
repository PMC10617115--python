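"""Seeded synthetic LPI data with known ground truth.

Two generator flavors:

* **feature-level** (`generate_feature_dataset`): a pair-feature matrix of
  standard-normal columns in which a small planted subset of "informative"
  columns drives the labels through a logistic model.  The intercept is
  calibrated by bisection so the positive prevalence matches the requested
  fraction, and the generator reports the numerically integrated Bayes
  AUROC of its own model — the ceiling any classifier can reach on the
  observed features.  This isolates the selection loop from featurization.

* **sequence-level** (`generate_motif_dataset`): random lncRNA / protein
  sequences in which a nucleotide motif and an amino-acid motif are planted
  in a fraction of each class; a pair interacts with elevated probability
  when both partners carry their motif.  Written out as FASTA + pair-list
  files so the whole featurization pipeline can be exercised end to end;
  the ground truth records which k-mer features the motifs enrich.

Everything is a pure function of its spec (seed included).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy.special import expit, roots_hermitenorm

from ._seeds import derive_seed
from .featurization import (
    AMINO_ACID,
    NUCLEOTIDE,
    _CANONICAL,
    FeatureSpec,
    PairDataset,
    SequenceRecord,
)

__all__ = [
    "SyntheticSpec",
    "MotifSpec",
    "GroundTruth",
    "generate_sequences",
    "generate_feature_dataset",
    "generate_motif_dataset",
    "bayes_auroc_logistic_normal",
]


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the feature-level generator."""

    n_samples: int = 500
    n_features: int = 200
    n_informative: int = 5
    effect_size: float = 2.0  # log-odds weight of each informative column
    noise_sd: float = 0.0  # measurement noise added to informative columns
    pos_fraction: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.pos_fraction < 1:
            raise ValueError("pos_fraction must be in (0, 1)")
        if self.n_informative > self.n_features:
            raise ValueError("n_informative exceeds n_features")


@dataclass
class GroundTruth:
    """What the generator planted: the causal columns and their model."""

    informative_indices: list[int]
    generating_coefficients: list[float]
    intercept: float
    bayes_auroc: float
    generating_probs: np.ndarray | None = None

    def label_probability(self, X_latent: np.ndarray) -> np.ndarray:
        """P(y=1 | latent informative columns) under the generating model."""
        beta = np.asarray(self.generating_coefficients)
        return expit(self.intercept + X_latent[:, self.informative_indices] @ beta)


def generate_sequences(
    count: int,
    length: int,
    alphabet: str,
    seed: int,
    id_prefix: str | None = None,
) -> list[SequenceRecord]:
    """i.i.d.-uniform random sequences with ids like ``lnc0001``."""
    if count < 1 or length < 1:
        raise ValueError("count and length must be >= 1")
    if id_prefix is None:
        id_prefix = "lnc" if alphabet == NUCLEOTIDE else "prot"
    symbols = list(_CANONICAL[alphabet])
    rng = np.random.default_rng(seed)
    return [
        SequenceRecord(
            f"{id_prefix}{i + 1:04d}",
            "".join(rng.choice(symbols, size=length)),
            alphabet,
        )
        for i in range(count)
    ]


def _gh_expect_sigmoid(mean, sd, nodes=None):
    """E[sigmoid(mean + sd*Z)], Z ~ N(0,1), by Gauss-Hermite quadrature.

    ``mean`` may be an array; ``sd`` is scalar.
    """
    if nodes is None:
        nodes = roots_hermitenorm(64)
    x, wq = nodes
    wq = wq / np.sqrt(2 * np.pi)
    mean = np.atleast_1d(np.asarray(mean, dtype=float))
    vals = expit(mean[:, None] + sd * x[None, :]) @ wq
    return vals


def _calibrate_intercept(sigma: float, pos_fraction: float, tol: float = 0.01) -> float:
    """Bisection on b0 so that E[sigmoid(b0 + sigma*Z)] = pos_fraction."""
    if sigma == 0.0:
        return float(np.log(pos_fraction / (1 - pos_fraction)))
    lo, hi = -30.0, 30.0
    nodes = roots_hermitenorm(64)
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        prev = float(_gh_expect_sigmoid(mid, sigma, nodes)[0])
        if abs(prev - pos_fraction) <= tol / 10:
            return mid
        if prev < pos_fraction:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def bayes_auroc_logistic_normal(
    coefficients,
    intercept: float,
    noise_sd: float = 0.0,
    grid_size: int = 4001,
) -> float:
    """Bayes-optimal AUROC of the logistic-normal generating model.

    Labels follow y ~ Bernoulli(sigmoid(b0 + beta.z)) with z standard
    normal; the observed informative columns are x = z + noise_sd * e.  The
    optimal observed score is monotone in s = beta.x, so the optimum AUROC
    is P(s_pos > s_neg), computed by quadrature: eta(s) = E[sigmoid(t)|s]
    via Gauss-Hermite over the conditional normal of t = b0 + beta.z given
    s, then a trapezoid integral of the class-conditional densities of s.
    """
    beta = np.asarray(coefficients, dtype=float)
    var_t = float(beta @ beta)  # Var(beta.z)
    if var_t == 0.0:
        return 0.5
    var_s = var_t * (1.0 + noise_sd**2)
    cov = var_t
    sd_s = np.sqrt(var_s)
    s = np.linspace(-8 * sd_s, 8 * sd_s, grid_size)
    # t - b0 | s  ~  N(cov/var_s * s, var_t - cov^2/var_s)
    cond_mean = intercept + (cov / var_s) * s
    cond_sd = np.sqrt(max(var_t - cov**2 / var_s, 0.0))
    eta = _gh_expect_sigmoid(cond_mean, cond_sd)
    phi = np.exp(-0.5 * (s / sd_s) ** 2) / (sd_s * np.sqrt(2 * np.pi))
    p1 = phi * eta
    p0 = phi * (1.0 - eta)
    pi1 = np.trapezoid(p1, s)
    pi0 = np.trapezoid(p0, s)
    # P(s1 > s2), s1 ~ p1/pi1, s2 ~ p0/pi0: integrate p1 against the CDF of p0
    ds = s[1] - s[0]
    cdf0 = np.cumsum(p0) * ds - 0.5 * p0 * ds  # midpoint-corrected running CDF
    return float(np.trapezoid(p1 * cdf0, s) / (pi1 * pi0))


def generate_feature_dataset(spec: SyntheticSpec) -> tuple[PairDataset, GroundTruth]:
    """Planted-signal feature matrix + labels + ground truth (see module doc)."""
    rng = np.random.default_rng(spec.seed)
    n, p = spec.n_samples, spec.n_features
    Z = rng.standard_normal((n, p))
    informative = np.sort(
        rng.choice(p, size=spec.n_informative, replace=False)
    ).tolist()
    beta = np.full(spec.n_informative, float(spec.effect_size))
    sigma = float(np.sqrt(beta @ beta))
    b0 = _calibrate_intercept(sigma, spec.pos_fraction)
    logits = b0 + Z[:, informative] @ beta
    probs = expit(logits)
    labels = (rng.random(n) < probs).astype(np.int64)
    X = Z.copy()
    if spec.noise_sd > 0:
        X[:, informative] += spec.noise_sd * rng.standard_normal((n, spec.n_informative))
    gt = GroundTruth(
        informative_indices=informative,
        generating_coefficients=beta.tolist(),
        intercept=b0,
        bayes_auroc=bayes_auroc_logistic_normal(beta, b0, spec.noise_sd),
        generating_probs=probs,
    )
    names = [f"lnc:s{i}" if i < p // 2 else f"prot:s{i}" for i in range(p)]
    pair_ids = [(f"lnc{i:05d}", f"prot{i:05d}") for i in range(n)]
    ds = PairDataset(
        X, labels, names, pair_ids, provenance={"generator": "feature", **asdict(spec)}
    )
    return ds, gt


@dataclass(frozen=True)
class MotifSpec:
    """Parameters of the sequence-level (motif) generator."""

    n_lnc: int = 30
    n_prot: int = 20
    lnc_length: int = 200
    prot_length: int = 120
    lnc_motif: str = "GCATTGGCAT"
    prot_motif: str = "WYKRW"
    insertion_fraction: float = 0.5
    p_interact_co: float = 0.9  # P(interaction | both carry their motif)
    p_background: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.lnc_motif) > self.lnc_length:
            raise ValueError("lncRNA motif longer than sequence")
        if len(self.prot_motif) > self.prot_length:
            raise ValueError("protein motif longer than sequence")


def _plant(seq: str, motif: str, rng) -> str:
    pos = int(rng.integers(0, len(seq) - len(motif) + 1))
    return seq[:pos] + motif + seq[pos + len(motif) :]


def _motif_kmers(motif: str, ks, prefix: str) -> list[str]:
    out = []
    for k in ks:
        for i in range(len(motif) - k + 1):
            out.append(f"{prefix}k{k}:{motif[i : i + k]}")
    return sorted(set(out))


def generate_motif_dataset(
    spec: MotifSpec,
    out_dir,
    feature_spec: FeatureSpec = FeatureSpec(),
) -> dict:
    """Write FASTA files + positive-pair list + ground-truth JSON.

    Returns a dict with the written paths, the carrier ids, and the k-mer
    feature names the planted motifs enrich.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)

    lncs = generate_sequences(
        spec.n_lnc, spec.lnc_length, NUCLEOTIDE, derive_seed(spec.seed, 1)
    )
    prots = generate_sequences(
        spec.n_prot, spec.prot_length, AMINO_ACID, derive_seed(spec.seed, 2)
    )
    lnc_carriers = set(
        r.id for r in lncs if rng.random() < spec.insertion_fraction
    )
    prot_carriers = set(
        r.id for r in prots if rng.random() < spec.insertion_fraction
    )
    lncs = [
        SequenceRecord(r.id, _plant(r.sequence, spec.lnc_motif, rng), r.alphabet)
        if r.id in lnc_carriers
        else r
        for r in lncs
    ]
    prots = [
        SequenceRecord(r.id, _plant(r.sequence, spec.prot_motif, rng), r.alphabet)
        if r.id in prot_carriers
        else r
        for r in prots
    ]

    positives = []
    for l in lncs:
        for p in prots:
            co = l.id in lnc_carriers and p.id in prot_carriers
            prob = spec.p_interact_co if co else spec.p_background
            if rng.random() < prob:
                positives.append((l.id, p.id))

    lnc_path = out_dir / "lnc.fasta"
    prot_path = out_dir / "prot.fasta"
    pairs_path = out_dir / "pairs.tsv"
    gt_path = out_dir / "ground_truth.json"
    for path, records in ((lnc_path, lncs), (prot_path, prots)):
        with open(path, "w") as fh:
            for r in records:
                fh.write(f">{r.id}\n{r.sequence}\n")
    with open(pairs_path, "w") as fh:
        for l, p in positives:
            fh.write(f"{l}\t{p}\n")

    truth = {
        "lnc_motif": spec.lnc_motif,
        "prot_motif": spec.prot_motif,
        "lnc_carriers": sorted(lnc_carriers),
        "prot_carriers": sorted(prot_carriers),
        "n_positive": len(positives),
        "enriched_features": _motif_kmers(
            spec.lnc_motif, feature_spec.nucleotide_k, "lnc:"
        )
        + _motif_kmers(spec.prot_motif, feature_spec.amino_acid_k, "prot:"),
        "spec": asdict(spec),
    }
    gt_path.write_text(json.dumps(truth, indent=2))
    return {
        "lnc_fasta": lnc_path,
        "prot_fasta": prot_path,
        "pairs": pairs_path,
        "ground_truth": gt_path,
        **truth,
    }
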