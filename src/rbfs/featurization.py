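"""Sequence featurization and pair-dataset assembly.

Turns lncRNA and protein FASTA files plus a positive-interaction pair list
into a labelled feature matrix: each lncRNA-protein pair is represented by
the concatenation of the two partners' k-mer composition vectors, labelled 1
for a known interaction and 0 for a sampled non-interacting pair.

k-mer composition is the normalized count of every overlapping length-k
substring over the declared alphabet, in lexicographic order.  Defaults:
k in {1,2,3,4} for nucleotide sequences (4+16+64+256 = 340 features) and
k in {1,2} for amino acids (20+400 = 420 features), giving 760-dimensional
pair vectors.

Ambiguity handling: sequences are uppercased; ``U`` is mapped to ``T`` in
nucleotide sequences; other ambiguity codes (``N``, ``X``, ``B``, ``Z``,
``J``, ...) are tolerated in the input but excluded from k-mer counting —
only windows consisting entirely of canonical symbols are counted, and the
normalizing denominator is the number of such valid windows.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import SeqIO

from ._seeds import derive_seed

__all__ = [
    "NUCLEOTIDE",
    "AMINO_ACID",
    "SequenceRecord",
    "InteractionMatrix",
    "PairDataset",
    "FeatureSpec",
    "read_fasta",
    "read_pair_list",
    "kmer_composition",
    "featurize_sequences",
    "sample_negatives",
    "build_pair_dataset",
]

NUCLEOTIDE = "nucleotide"
AMINO_ACID = "amino-acid"

_CANONICAL = {
    NUCLEOTIDE: "ACGT",
    AMINO_ACID: "ACDEFGHIKLMNPQRSTVWY",
}
# symbols tolerated in input sequences but excluded from k-mer windows
_AMBIGUOUS = {
    NUCLEOTIDE: set("NRYSWKMBDHV-"),
    AMINO_ACID: set("XBZJUO*-"),
}


@dataclass(frozen=True)
class SequenceRecord:
    """One FASTA entry: identifier, uppercased residue string, alphabet tag."""

    id: str
    sequence: str
    alphabet: str

    def __post_init__(self) -> None:
        if self.alphabet not in _CANONICAL:
            raise ValueError(f"unknown alphabet {self.alphabet!r}")
        if not self.sequence:
            raise ValueError(f"record {self.id!r}: empty sequence")
        allowed = set(_CANONICAL[self.alphabet]) | _AMBIGUOUS[self.alphabet]
        bad = set(self.sequence) - allowed
        if bad:
            raise ValueError(
                f"record {self.id!r}: symbols {sorted(bad)} outside "
                f"{self.alphabet} alphabet"
            )


def _normalize(seq: str, alphabet: str) -> str:
    seq = seq.upper()
    if alphabet == NUCLEOTIDE:
        seq = seq.replace("U", "T")
    return seq


def read_fasta(path, alphabet: str) -> list[SequenceRecord]:
    """Read a FASTA file into validated :class:`SequenceRecord` objects.

    Raises ``ValueError`` on an empty file, a duplicate identifier, or a
    symbol outside the declared alphabet (the offending record is named).
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate id {rec.id!r} in {path}")
        seen.add(rec.id)
        records.append(
            SequenceRecord(rec.id, _normalize(str(rec.seq), alphabet), alphabet)
        )
    if not records:
        raise ValueError(f"no records in {path}")
    return records


def read_pair_list(path) -> list[tuple[str, str]]:
    """Read a 2-column tab-separated (lnc_id, prot_id) list, no header."""
    pairs: list[tuple[str, str]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected 2 tab-separated columns")
            pairs.append((parts[0], parts[1]))
    if not pairs:
        raise ValueError(f"no pairs in {path}")
    return pairs


@dataclass
class InteractionMatrix:
    """Binary lncRNA x protein interaction matrix Y (1 = interaction)."""

    lnc_ids: list[str]
    prot_ids: list[str]
    y: np.ndarray

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y)
        if self.y.shape != (len(self.lnc_ids), len(self.prot_ids)):
            raise ValueError("y shape does not match id lists")
        if not np.isin(self.y, (0, 1)).all():
            raise ValueError("interaction matrix entries must be 0 or 1")

    @classmethod
    def from_pairs(
        cls,
        positives: list[tuple[str, str]],
        lnc_ids: list[str] | None = None,
        prot_ids: list[str] | None = None,
    ) -> "InteractionMatrix":
        """Build Y from a positive pair list; id universes default to the
        ids occurring in the list (insertion order)."""
        if lnc_ids is None:
            lnc_ids = list(dict.fromkeys(l for l, _ in positives))
        if prot_ids is None:
            prot_ids = list(dict.fromkeys(p for _, p in positives))
        li = {v: i for i, v in enumerate(lnc_ids)}
        pi = {v: i for i, v in enumerate(prot_ids)}
        y = np.zeros((len(lnc_ids), len(prot_ids)), dtype=np.int8)
        for l, p in positives:
            if l not in li:
                raise KeyError(f"lncRNA id {l!r} not in id universe")
            if p not in pi:
                raise KeyError(f"protein id {p!r} not in id universe")
            y[li[l], pi[p]] = 1
        return cls(lnc_ids, prot_ids, y)

    def positives(self) -> list[tuple[str, str]]:
        return [
            (self.lnc_ids[i], self.prot_ids[j]) for i, j in zip(*np.nonzero(self.y))
        ]


@dataclass
class PairDataset:
    """Labelled pair-feature matrix: n pairs x p features.

    Rows are [lnc features || prot features]; ``feature_names`` carry an
    origin prefix (``lnc:`` / ``prot:``); ``pair_ids`` are unique
    (lnc_id, prot_id) tuples.
    """

    X: np.ndarray
    labels: np.ndarray
    feature_names: list[str]
    pair_ids: list[tuple[str, str]]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.X.ndim != 2:
            raise ValueError("X must be 2-D")
        n, p = self.X.shape
        if len(self.labels) != n or len(self.pair_ids) != n:
            raise ValueError("labels / pair_ids length mismatch with X")
        if len(self.feature_names) != p:
            raise ValueError("feature_names length mismatch with X")
        if len(set(self.pair_ids)) != n:
            raise ValueError("duplicate pair_ids")
        if len(set(self.feature_names)) != p:
            raise ValueError("duplicate feature_names")

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.X, columns=self.feature_names)
        df.insert(0, "pair_id", [f"{l}|{p}" for l, p in self.pair_ids])
        df["label"] = self.labels
        return df

    def write_table(self, path, sep: str = "\t") -> None:
        """First column pair id 'lnc|prot', header row, final column 'label'."""
        self.to_frame().to_csv(path, sep=sep, index=False)

    @classmethod
    def read_table(cls, path, sep: str = "\t") -> "PairDataset":
        df = pd.read_csv(path, sep=sep)
        if df.columns[0] != "pair_id" or df.columns[-1] != "label":
            raise ValueError(
                f"{path}: expected first column 'pair_id' and last column 'label'"
            )
        pair_ids = [tuple(s.split("|", 1)) for s in df["pair_id"].astype(str)]
        names = list(df.columns[1:-1])
        return cls(
            df[names].to_numpy(dtype=float),
            df["label"].to_numpy(),
            names,
            pair_ids,
            provenance={"source": str(path)},
        )


@dataclass(frozen=True)
class FeatureSpec:
    """k values per alphabet for k-mer composition features."""

    nucleotide_k: tuple[int, ...] = (1, 2, 3, 4)
    amino_acid_k: tuple[int, ...] = (1, 2)

    def ks(self, alphabet: str) -> tuple[int, ...]:
        return self.nucleotide_k if alphabet == NUCLEOTIDE else self.amino_acid_k

    def dimension(self, alphabet: str) -> int:
        a = len(_CANONICAL[alphabet])
        return sum(a**k for k in self.ks(alphabet))


def _kmer_names(alphabet: str, k: int) -> list[str]:
    return ["".join(t) for t in itertools.product(_CANONICAL[alphabet], repeat=k)]


def kmer_composition(seq: str, k: int, alphabet: str) -> np.ndarray:
    """Frequency vector over all |alphabet|^k k-mers, lexicographic order.

    Overlapping windows; windows containing a non-canonical symbol are
    skipped and excluded from the denominator.  The returned vector sums to
    1 whenever at least one valid window exists.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    seq = _normalize(seq, alphabet)
    if len(seq) < k:
        raise ValueError(f"sequence of length {len(seq)} shorter than k={k}")
    symbols = _CANONICAL[alphabet]
    index = {c: i for i, c in enumerate(symbols)}
    base = len(symbols)
    counts = np.zeros(base**k, dtype=float)
    valid = 0
    for i in range(len(seq) - k + 1):
        window = seq[i : i + k]
        idx = 0
        for c in window:
            j = index.get(c)
            if j is None:
                idx = -1
                break
            idx = idx * base + j
        if idx >= 0:
            counts[idx] += 1
            valid += 1
    if valid == 0:
        raise ValueError(f"no valid {k}-mer window in sequence")
    return counts / valid


def featurize_sequences(
    records: list[SequenceRecord],
    spec: FeatureSpec = FeatureSpec(),
    prefix: str = "",
) -> tuple[dict[str, np.ndarray], list[str]]:
    """Compute per-record k-mer composition vectors.

    Returns a mapping id -> concatenated feature vector (one block per k in
    the spec) and the matching feature names, e.g. ``lnc:k2:AC`` when
    ``prefix="lnc:"``.  A record violating the k-mer preconditions is
    reported with its id.
    """
    if not records:
        raise ValueError("no records to featurize")
    alphabets = {r.alphabet for r in records}
    if len(alphabets) != 1:
        raise ValueError("records mix alphabets")
    alphabet = alphabets.pop()
    ks = spec.ks(alphabet)
    names = [f"{prefix}k{k}:{name}" for k in ks for name in _kmer_names(alphabet, k)]
    feats: dict[str, np.ndarray] = {}
    for rec in records:
        try:
            blocks = [kmer_composition(rec.sequence, k, alphabet) for k in ks]
        except ValueError as exc:
            raise ValueError(f"record {rec.id!r}: {exc}") from exc
        feats[rec.id] = np.concatenate(blocks)
    return feats, names


def sample_negatives(
    interactions: InteractionMatrix,
    ratio: float,
    seed: int,
) -> list[tuple[str, str]]:
    """Sample non-interacting pairs uniformly from the zero entries of Y.

    ``round(ratio * positives)`` pairs are drawn without replacement;
    reproducible given ``seed``.  Raises if too few zero entries exist,
    stating the maximum feasible count.
    """
    if ratio <= 0:
        raise ValueError("ratio must be positive")
    zi, zj = np.nonzero(interactions.y == 0)
    n_pos = int(interactions.y.sum())
    want = int(round(ratio * n_pos))
    if want == 0:
        raise ValueError("requested zero negatives; increase ratio")
    if want > len(zi):
        raise ValueError(
            f"cannot sample {want} negatives: only {len(zi)} non-interacting "
            "pairs available"
        )
    rng = np.random.default_rng(derive_seed(seed, 101))
    pick = rng.choice(len(zi), size=want, replace=False)
    return [
        (interactions.lnc_ids[zi[t]], interactions.prot_ids[zj[t]]) for t in pick
    ]


def build_pair_dataset(
    lnc_feats: dict[str, np.ndarray],
    prot_feats: dict[str, np.ndarray],
    positives: list[tuple[str, str]],
    negatives: list[tuple[str, str]],
    lnc_names: list[str] | None = None,
    prot_names: list[str] | None = None,
) -> PairDataset:
    """Assemble the labelled pair matrix: row = [lnc vector || prot vector].

    Positives are labelled 1, negatives 0.  Any pair id that does not
    resolve to a feature vector raises ``KeyError`` naming it.
    """
    d_lnc = len(next(iter(lnc_feats.values()))) if lnc_feats else 0
    d_prot = len(next(iter(prot_feats.values()))) if prot_feats else 0
    if lnc_names is None:
        lnc_names = [f"lnc:f{i}" for i in range(d_lnc)]
    if prot_names is None:
        prot_names = [f"prot:f{i}" for i in range(d_prot)]
    names = [n if n.startswith("lnc:") else f"lnc:{n}" for n in lnc_names] + [
        n if n.startswith("prot:") else f"prot:{n}" for n in prot_names
    ]
    rows, labels, pair_ids = [], [], []
    for pairs, label in ((positives, 1), (negatives, 0)):
        for l, p in pairs:
            if l not in lnc_feats:
                raise KeyError(f"lncRNA id {l!r} has no feature vector")
            if p not in prot_feats:
                raise KeyError(f"protein id {p!r} has no feature vector")
            rows.append(np.concatenate([lnc_feats[l], prot_feats[p]]))
            labels.append(label)
            pair_ids.append((l, p))
    X = np.vstack(rows) if rows else np.empty((0, d_lnc + d_prot))
    return PairDataset(X, np.array(labels, dtype=np.int64), names, pair_ids)
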