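"""Canonical seed-match miRNA target prediction and gene-set enrichment.

Target sites are the canonical seed-complementarity classes.  With the miRNA
seed defined as nucleotides 2-8 (5'->3') and patterns expressed on the mRNA
sense strand in DNA alphabet:

* ``7mer-m8``: reverse complement of seed positions 2-8;
* ``8mer``: the 7mer-m8 match followed by an A;
* ``7mer-A1``: reverse complement of positions 2-7 followed by an A.

Sites are classified hierarchically (an 8mer is not double-reported as its
constituent 7mers) but overlapping sites of distinct classes are all
reported.  Coordinates are 0-based half-open on the UTR.  Enrichment is the
upper-tail hypergeometric test with Benjamini-Hochberg control at FDR 10%.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import GeneSetAnnotation, SequenceSet, TargetMap
from .diffexpr import bh_adjust

__all__ = ["SeedSite", "seed_patterns", "predict_targets", "enrich", "enrich_mirna_module"]

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def _revcomp(dna: str) -> str:
    return dna.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class SeedSite:
    mirna: str
    utr: str
    start: int  # 0-based, + strand, UTR orientation
    site_type: str  # "8mer" | "7mer-m8" | "7mer-A1"

    @property
    def length(self) -> int:
        return 8 if self.site_type == "8mer" else 7

    @property
    def end(self) -> int:
        return self.start + self.length


def seed_patterns(mirna_seq: str) -> dict[str, str]:
    """DNA-alphabet site patterns for one miRNA sequence (>= 8 nt, RNA or DNA)."""
    dna = mirna_seq.upper().replace("U", "T")
    if len(dna) < 8:
        raise ValueError("miRNA shorter than 8 nt has no defined seed")
    seed_2_8 = dna[1:8]
    seed_2_7 = dna[1:7]
    m8 = _revcomp(seed_2_8)
    return {"8mer": m8 + "A", "7mer-m8": m8, "7mer-A1": _revcomp(seed_2_7) + "A"}


def _find_all(haystack: str, needle: str) -> list[int]:
    out, start = [], 0
    while True:
        i = haystack.find(needle, start)
        if i < 0:
            return out
        out.append(i)
        start = i + 1


def predict_targets(
    mirnas: SequenceSet,
    utrs: SequenceSet,
    expressed: set[str] | None = None,
) -> tuple[list[SeedSite], TargetMap]:
    """Scan every UTR (sense strand) for canonical seed sites of every miRNA.

    ``expressed`` optionally restricts the target universe to genes measured
    as expressed; the returned :class:`TargetMap` contains genes with at
    least one site, intersected with that filter.  miRNAs shorter than 8 nt
    are skipped with a warning.  Site classification is hierarchical:
    8mer > 7mer-m8 > 7mer-A1 at overlapping positions.
    """
    sites: list[SeedSite] = []
    targets: dict[str, set[str]] = {}
    universe = set(utrs.sequences) if expressed is None else set(expressed)
    for mirna_id in sorted(mirnas.sequences):
        seq = mirnas[mirna_id]
        if len(seq) < 8:
            warnings.warn(f"miRNA {mirna_id!r} shorter than 8 nt; skipped")
            continue
        patterns = seed_patterns(seq)
        for utr_id in sorted(utrs.sequences):
            utr = utrs[utr_id].replace("U", "T")
            eightmer_starts = set(_find_all(utr, patterns["8mer"]))
            found: list[tuple[int, str]] = [(s, "8mer") for s in eightmer_starts]
            for s in _find_all(utr, patterns["7mer-m8"]):
                if s not in eightmer_starts:  # not the m8 half of an 8mer
                    found.append((s, "7mer-m8"))
            for s in _find_all(utr, patterns["7mer-A1"]):
                if s - 1 not in eightmer_starts:  # not the A1 half of an 8mer
                    found.append((s, "7mer-A1"))
            for start, site_type in sorted(found):
                sites.append(SeedSite(mirna_id, utr_id, start, site_type))
            if found and (expressed is None or utr_id in universe):
                targets.setdefault(mirna_id, set()).add(utr_id)
    tmap = TargetMap({m: frozenset(g) for m, g in targets.items()}, frozenset(universe))
    return sites, tmap


def enrich(
    selection: set[str],
    universe: set[str],
    annotation: GeneSetAnnotation,
    fdr: float = 0.10,
    report_untested: bool = False,
) -> pd.DataFrame:
    """Upper-tail hypergeometric over-representation of each term in a selection.

    ``p = P[X >= k]`` for overlap k, term size K (within the universe),
    selection size n and universe size N; BH adjustment is computed across
    the tested terms only (terms with K = 0 or k = 0 are skipped, or reported
    with p = 1 when ``report_untested``).
    """
    selection, universe = set(selection), set(universe)
    stray = selection - universe
    if stray:
        raise ValueError(f"selection not contained in universe: {sorted(stray)[:5]!r}")
    n = len(selection)
    N = len(universe)
    tested_rows, skipped_rows = [], []
    for term in sorted(annotation.terms):
        members = annotation.terms[term] & universe
        K = len(members)
        k = len(members & selection)
        row = {"term": term, "k": k, "K": K, "n": n, "N": N}
        if K == 0 or k == 0 or K >= N:
            if report_untested:
                skipped_rows.append({**row, "p": 1.0, "q": np.nan, "enriched": False})
            continue
        row["p"] = float(stats.hypergeom.sf(k - 1, N, K, n))
        tested_rows.append(row)
    frame = pd.DataFrame(tested_rows, columns=["term", "k", "K", "n", "N", "p"])
    if len(frame):
        frame["q"] = bh_adjust(frame["p"].to_numpy())
        frame["enriched"] = frame["q"] <= fdr
    else:
        frame["q"] = pd.Series(dtype=float)
        frame["enriched"] = pd.Series(dtype=bool)
    if skipped_rows:
        frame = pd.concat([frame, pd.DataFrame(skipped_rows)], ignore_index=True)
    return frame.sort_values(["p", "term"], na_position="last").reset_index(drop=True)


def enrich_mirna_module(
    hub_mirnas: list[str],
    targetmap: TargetMap,
    universe: set[str],
    annotation: GeneSetAnnotation,
    fdr: float = 0.10,
) -> pd.DataFrame:
    """Enrichment of the union of hub-miRNA target genes (set semantics)."""
    selection: set[str] = set()
    for hub in hub_mirnas:
        selection |= set(targetmap.targets.get(hub, frozenset()))
    selection &= set(universe)
    if not selection:
        warnings.warn("hub miRNAs have no targets in the universe; empty enrichment")
        return pd.DataFrame(columns=["term", "k", "K", "n", "N", "p", "q", "enriched"])
    return enrich(selection, universe, annotation, fdr=fdr)
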