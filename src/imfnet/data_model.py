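"""Core data containers and readers/writers for the integrative co-expression pipeline.

All tabular formats are tab-separated with a header row; count tables carry
feature ids in the first column and sample ids in the header.  Phenotype
tables are one row per animal with named columns (``sample_id``,
``imf_percent``, ``gebv``, ``group`` required; ``age_days``,
``contemporary_group`` and ``mapped_reads`` optional).  Gene-set annotation
is accepted as GMT or two-column TSV, 3'UTR sequences as FASTA.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CountMatrix",
    "ExpressionMatrix",
    "PhenotypeTable",
    "GeneSetAnnotation",
    "TargetMap",
    "SequenceSet",
    "read_counts",
    "write_counts",
    "read_phenotypes",
    "write_phenotypes",
    "load_study_phenotypes",
    "summarize_phenotypes",
    "compare_groups",
    "read_annotation",
    "write_annotation_gmt",
    "read_fasta",
    "write_fasta",
]

LAYERS = ("mRNA", "miRNA")

_REQUIRED_PHENO_COLUMNS = ("sample_id", "imf_percent", "gebv", "group")
_OPTIONAL_PHENO_COLUMNS = ("age_days", "contemporary_group", "mapped_reads")

_NUCLEOTIDES = frozenset("ACGTUN")


class FormatError(ValueError):
    """Raised when an input file violates the expected format."""


def _check_unique(ids: Iterable[str], kind: str) -> list[str]:
    ids = list(ids)
    seen: set[str] = set()
    for i in ids:
        if i in seen:
            raise FormatError(f"duplicate {kind} id: {i!r}")
        seen.add(i)
    return ids


@dataclass
class CountMatrix:
    """Raw feature x sample counts for one expression layer (mRNA or miRNA)."""

    values: np.ndarray
    feature_ids: list[str]
    sample_ids: list[str]
    layer: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.layer not in LAYERS:
            raise ValueError(f"layer must be one of {LAYERS}, got {self.layer!r}")
        if self.values.ndim != 2:
            raise ValueError("count matrix must be two-dimensional")
        if not np.issubdtype(self.values.dtype, np.integer):
            if np.any(self.values != np.floor(self.values)):
                raise FormatError("counts must be integers")
            self.values = self.values.astype(np.int64)
        if np.any(self.values < 0):
            raise FormatError("counts must be non-negative")
        self.feature_ids = _check_unique(self.feature_ids, "feature")
        self.sample_ids = _check_unique(self.sample_ids, "sample")
        if self.values.shape != (len(self.feature_ids), len(self.sample_ids)):
            raise ValueError(
                f"shape {self.values.shape} does not match "
                f"{len(self.feature_ids)} features x {len(self.sample_ids)} samples"
            )

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.feature_ids, columns=self.sample_ids)


@dataclass
class ExpressionMatrix:
    """log2(normalized count + pseudocount) values on the same ids as the source counts."""

    values: np.ndarray
    feature_ids: list[str]
    sample_ids: list[str]
    size_factors_used: np.ndarray
    pseudocount: float = 1.0
    layer: str | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.size_factors_used = np.asarray(self.size_factors_used, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("expression values must be finite")
        if np.any(self.size_factors_used <= 0):
            raise ValueError("size factors must be positive")
        if self.pseudocount <= 0:
            raise ValueError("pseudocount must be positive")

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.feature_ids, columns=self.sample_ids)

    def subset_samples(self, sample_ids: Iterable[str]) -> "ExpressionMatrix":
        wanted = list(sample_ids)
        idx = [self.sample_ids.index(s) for s in wanted]
        return ExpressionMatrix(
            self.values[:, idx],
            list(self.feature_ids),
            wanted,
            self.size_factors_used[idx],
            self.pseudocount,
            self.layer,
        )

    def subset_features(self, feature_ids: Iterable[str]) -> "ExpressionMatrix":
        wanted = list(feature_ids)
        pos = {f: i for i, f in enumerate(self.feature_ids)}
        idx = [pos[f] for f in wanted]
        return ExpressionMatrix(
            self.values[idx, :],
            wanted,
            list(self.sample_ids),
            self.size_factors_used,
            self.pseudocount,
            self.layer,
        )


@dataclass
class PhenotypeTable:
    """Per-animal phenotypes: IMF %, GEBV, H/L group, optional covariates."""

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.frame
        for col in _REQUIRED_PHENO_COLUMNS:
            if col not in df.columns:
                raise FormatError(f"phenotype table missing required column {col!r}")
        if len(df) == 0:
            raise FormatError("no samples in phenotype table")
        _check_unique(df["sample_id"].astype(str), "sample")
        bad = set(df["group"]) - {"H", "L"}
        if bad:
            raise FormatError(f"unknown group label(s): {sorted(bad)!r} (expected H or L)")
        self.frame = df.reset_index(drop=True)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.frame["sample_id"].astype(str))

    @property
    def groups(self) -> pd.Series:
        return self.frame["group"]

    def samples_in_group(self, group: str) -> list[str]:
        return list(self.frame.loc[self.frame["group"] == group, "sample_id"].astype(str))

    def column(self, name: str) -> pd.Series:
        if name not in self.frame.columns:
            raise KeyError(f"no phenotype column {name!r}")
        return self.frame[name]


@dataclass
class GeneSetAnnotation:
    """Term -> member-gene sets, e.g. GO biological-process annotation."""

    terms: dict[str, frozenset[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for term, members in self.terms.items():
            if not members:
                raise ValueError(f"term {term!r} has no members")
        self.terms = {t: frozenset(m) for t, m in self.terms.items()}

    def __len__(self) -> int:
        return len(self.terms)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GeneSetAnnotation):
            return NotImplemented
        return self.terms == other.terms


@dataclass
class TargetMap:
    """miRNA id -> set of predicted target gene ids, within a declared universe."""

    targets: dict[str, frozenset[str]]
    universe: frozenset[str]

    def __post_init__(self) -> None:
        self.targets = {m: frozenset(g) for m, g in self.targets.items()}
        self.universe = frozenset(self.universe)
        for mirna, genes in self.targets.items():
            stray = genes - self.universe
            if stray:
                raise ValueError(
                    f"targets of {mirna!r} outside declared universe: {sorted(stray)[:5]!r}"
                )


@dataclass
class SequenceSet:
    """id -> nucleotide sequence over A/C/G/T/U/N (uppercase)."""

    sequences: dict[str, str]

    def __post_init__(self) -> None:
        for sid, seq in self.sequences.items():
            if not seq:
                raise FormatError(f"empty sequence for record {sid!r}")
            bad = set(seq.upper()) - _NUCLEOTIDES
            if bad:
                raise FormatError(
                    f"illegal characters {sorted(bad)!r} in sequence record {sid!r}"
                )
        self.sequences = {sid: seq.upper() for sid, seq in self.sequences.items()}

    def __len__(self) -> int:
        return len(self.sequences)

    def __getitem__(self, sid: str) -> str:
        return self.sequences[sid]

    def items(self):
        return self.sequences.items()


# ---------------------------------------------------------------------------
# readers / writers


def read_counts(path: str | Path, layer: str) -> CountMatrix:
    """Read a feature x sample count TSV (first column feature ids, header sample ids)."""
    df = pd.read_csv(path, sep="\t", header=0, dtype=str)
    if df.shape[1] < 2:
        raise FormatError(f"{path}: count table needs a feature-id column and >=1 sample")
    feature_ids = _check_unique(df.iloc[:, 0].astype(str), "feature")
    sample_ids = _check_unique((str(c) for c in df.columns[1:]), "sample")
    values = np.empty((len(feature_ids), len(sample_ids)), dtype=np.int64)
    for j, col in enumerate(df.columns[1:]):
        for i, cell in enumerate(df[col]):
            try:
                v = int(cell)
            except (TypeError, ValueError):
                raise FormatError(
                    f"{path}: non-integer count {cell!r} at feature "
                    f"{feature_ids[i]!r}, sample {sample_ids[j]!r}"
                ) from None
            if v < 0:
                raise FormatError(
                    f"{path}: negative count at feature {feature_ids[i]!r}, "
                    f"sample {sample_ids[j]!r}"
                )
            values[i, j] = v
    return CountMatrix(values, feature_ids, sample_ids, layer)


def write_counts(counts: CountMatrix, path: str | Path) -> None:
    """Write a count matrix in the canonical TSV dialect (LF line endings)."""
    with open(path, "w", newline="\n") as fh:
        fh.write("feature_id\t" + "\t".join(counts.sample_ids) + "\n")
        for i, fid in enumerate(counts.feature_ids):
            fh.write(fid + "\t" + "\t".join(str(v) for v in counts.values[i]) + "\n")


def read_phenotypes(path: str | Path) -> PhenotypeTable:
    """Read the per-animal phenotype TSV (IMF %, GEBV, H/L group, covariates)."""
    try:
        df = pd.read_csv(path, sep="\t", header=0, dtype=str)
    except pd.errors.EmptyDataError:
        raise FormatError(f"{path}: no samples (empty file)") from None
    if len(df) == 0:
        raise FormatError(f"{path}: no samples")
    for col in _REQUIRED_PHENO_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    numeric_cols = ["imf_percent", "gebv"] + [
        c for c in ("age_days", "mapped_reads") if c in df.columns
    ]
    for col in numeric_cols:
        parsed = pd.to_numeric(df[col], errors="coerce")
        bad = parsed.isna() & df[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise FormatError(
                f"{path}: non-numeric value {df[col].iloc[row]!r} in column "
                f"{col!r} at data row {row + 1}"
            )
        df[col] = parsed
    return PhenotypeTable(df)


def write_phenotypes(pheno: PhenotypeTable, path: str | Path) -> None:
    pheno.frame.to_csv(path, sep="\t", index=False, lineterminator="\n")


def load_study_phenotypes() -> PhenotypeTable:
    """Phenotypes of the 30 Nelore steers (15 high / 15 low IMF GEBV) shipped with the package."""
    ref = resources.files("imfnet.data").joinpath("nelore_imf_phenotypes.tsv")
    with resources.as_file(ref) as path:
        return read_phenotypes(path)


# ---------------------------------------------------------------------------
# phenotype statistics


def round_half_even(x: float, digits: int) -> float:
    """Round to ``digits`` decimals with ties going to the even digit."""
    from decimal import ROUND_HALF_EVEN, Decimal

    q = Decimal(1).scaleb(-digits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_EVEN))


def summarize_phenotypes(pheno: PhenotypeTable, column: str) -> pd.DataFrame:
    """Per-group mean, sd and n for a numeric phenotype column.

    Returns a frame indexed by group with columns ``mean``, ``sd``, ``n`` and
    ``sd_defined`` (False when a group has a single sample, in which case sd
    is reported as 0).
    """
    values = pd.to_numeric(pheno.column(column), errors="raise")
    rows = []
    for group in ("H", "L"):
        mask = (pheno.groups == group).to_numpy()
        n = int(mask.sum())
        if n == 0:
            raise ValueError(f"group {group!r} has no samples")
        x = values.to_numpy(dtype=float)[mask]
        sd_defined = n > 1
        rows.append(
            {
                "group": group,
                "mean": float(np.mean(x)),
                "sd": float(np.std(x, ddof=1)) if sd_defined else 0.0,
                "n": n,
                "sd_defined": sd_defined,
            }
        )
    return pd.DataFrame(rows).set_index("group")


def compare_groups(pheno: PhenotypeTable, column: str) -> tuple[float, float]:
    """Welch two-sample t-test (H vs L) on a numeric phenotype column.

    Returns ``(t, p)`` with a two-sided p-value.  If both groups are constant
    with equal means the test is degenerate and ``(0.0, 1.0)`` is returned by
    convention.
    """
    values = pd.to_numeric(pheno.column(column), errors="raise").to_numpy(dtype=float)
    h = values[(pheno.groups == "H").to_numpy()]
    l = values[(pheno.groups == "L").to_numpy()]
    if len(h) < 2 or len(l) < 2:
        raise ValueError("each group needs at least two samples for a t-test")
    if np.var(h) == 0 and np.var(l) == 0:
        if np.mean(h) == np.mean(l):
            return 0.0, 1.0
        return math.inf if np.mean(h) > np.mean(l) else -math.inf, 0.0
    t, p = stats.ttest_ind(h, l, equal_var=False)
    return float(t), float(p)


# ---------------------------------------------------------------------------
# annotation


def read_annotation(path: str | Path, fmt: str | None = None) -> GeneSetAnnotation:
    """Read gene-set annotation from GMT (term, description, members...) or
    two-column TSV (term, member) format.

    ``fmt`` may be ``"gmt"`` or ``"tsv"``; when omitted it is inferred from
    the file extension (``.gmt`` -> GMT, otherwise TSV).
    """
    path = Path(path)
    if fmt is None:
        fmt = "gmt" if path.suffix.lower() == ".gmt" else "tsv"
    terms: dict[str, set[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if fmt == "gmt":
                if len(fields) < 3:
                    raise FormatError(
                        f"{path}:{lineno}: GMT line needs term, description, >=1 member"
                    )
                term, desc, members = fields[0], fields[1], fields[2:]
            else:
                if len(fields) != 2:
                    raise FormatError(f"{path}:{lineno}: TSV annotation needs 2 columns")
                term, desc, members = fields[0], "", [fields[1]]
            if not term:
                warnings.warn(f"{path}:{lineno}: empty term id skipped")
                continue
            terms.setdefault(term, set()).update(m for m in members if m)
            if desc:
                descriptions[term] = desc
    empty = [t for t, m in terms.items() if not m]
    for t in empty:
        warnings.warn(f"term {t!r} has no members; skipped")
        del terms[t]
    if _has_duplicate_gmt_terms(path, fmt):
        raise FormatError(f"{path}: duplicate term id in GMT file")
    return GeneSetAnnotation({t: frozenset(m) for t, m in terms.items()}, descriptions)


def _has_duplicate_gmt_terms(path: Path, fmt: str) -> bool:
    if fmt != "gmt":
        return False
    seen: set[str] = set()
    with open(path) as fh:
        for line in fh:
            term = line.split("\t", 1)[0].strip()
            if not term:
                continue
            if term in seen:
                return True
            seen.add(term)
    return False


def write_annotation_gmt(annotation: GeneSetAnnotation, path: str | Path) -> None:
    with open(path, "w", newline="\n") as fh:
        for term in sorted(annotation.terms):
            desc = annotation.descriptions.get(term, "")
            members = "\t".join(sorted(annotation.terms[term]))
            fh.write(f"{term}\t{desc}\t{members}\n")


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> SequenceSet:
    """Read FASTA; record ids are headers up to the first whitespace, sequences uppercased."""
    from Bio import SeqIO

    sequences: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in sequences:
            raise FormatError(f"{path}: duplicate FASTA id {record.id!r}")
        sequences[record.id] = str(record.seq).upper()
    if not sequences:
        raise FormatError(f"{path}: no FASTA records")
    return SequenceSet(sequences)


def write_fasta(seqs: SequenceSet, path: str | Path, width: int = 70) -> None:
    with open(path, "w", newline="\n") as fh:
        for sid in seqs.sequences:
            fh.write(f">{sid}\n")
            seq = seqs.sequences[sid]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
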