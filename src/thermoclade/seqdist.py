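"""Haplotype collapsing and uncorrected p-distance summaries.

Uncorrected p-distances (proportion of differing sites, no multiple-hit
correction) are the standard descriptive companion to sequence-based
species delimitation: intraspecific distances should be small and
interspecific distances clearly larger.  Sites are compared under pairwise
deletion — only positions where both sequences carry an unambiguous
A/C/G/T are counted; gaps, N and IUPAC ambiguity codes are excluded.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from io import StringIO
from typing import Dict, List, Tuple, Union

import numpy as np
import pandas as pd
from Bio import SeqIO

__all__ = [
    "Alignment",
    "DistanceMatrix",
    "PartitionDistanceSummary",
    "read_fasta",
    "collapse_haplotypes",
    "p_distance_matrix",
    "partition_distance_summary",
]

_ALPHABET = set("ACGTRYSWKMBDHVN-?")
# code < 4 means unambiguous base
_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i
for _i, _b in enumerate("RYSWKMBDHVN-?"):
    _CODE[ord(_b)] = 4 + _i


@dataclass
class Alignment:
    """Equal-length DNA records; uppercase, U normalized to T."""

    ids: List[str]
    seqs: List[str]

    def __post_init__(self):
        if len(self.ids) != len(self.seqs):
            raise ValueError("ids and seqs differ in length")
        norm = []
        L = None
        for rid, s in zip(self.ids, self.seqs):
            s = s.upper().replace("U", "T")
            if L is None:
                L = len(s)
            elif len(s) != L:
                raise ValueError(f"ragged alignment: {rid!r} has length {len(s)} != {L}")
            bad = set(s) - _ALPHABET
            if bad:
                raise ValueError(f"illegal character(s) {sorted(bad)} in {rid!r}")
            norm.append(s)
        self.seqs = norm

    @property
    def n(self) -> int:
        return len(self.ids)

    @property
    def length(self) -> int:
        return len(self.seqs[0]) if self.seqs else 0

    def codes(self) -> np.ndarray:
        """(n, L) uint8 matrix; values < 4 are A/C/G/T."""
        return np.vstack(
            [_CODE[np.frombuffer(s.encode(), dtype=np.uint8)] for s in self.seqs]
        )

    def to_fasta(self) -> str:
        out = StringIO()
        for rid, s in zip(self.ids, self.seqs):
            out.write(f">{rid}\n{s}\n")
        return out.getvalue()


@dataclass
class DistanceMatrix:
    """Symmetric uncorrected p-distances with per-pair compared-site counts.

    Pairs with zero comparable sites are NaN (reported with a warning at
    construction time).
    """

    ids: List[str]
    values: np.ndarray
    compared: np.ndarray

    def __post_init__(self):
        v = self.values
        if v.shape[0] != v.shape[1] or v.shape[0] != len(self.ids):
            raise ValueError("matrix shape does not match ids")
        if not np.allclose(np.nan_to_num(v), np.nan_to_num(v.T)):
            raise ValueError("matrix not symmetric")
        if np.any(np.diag(v) != 0):
            raise ValueError("nonzero diagonal")
        with np.errstate(invalid="ignore"):
            if np.nanmin(v) < 0 or np.nanmax(v) > 1:
                raise ValueError("distances outside [0, 1]")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)

    def pair(self, a: str, b: str) -> float:
        return float(self.values[self.ids.index(a), self.ids.index(b)])


@dataclass
class PartitionDistanceSummary:
    """Intra/inter p-distance summary for a species partition.

    ``intra_max``/``intra_p95`` pool all within-species pairs (the
    percentile uses linear interpolation between order statistics);
    ``per_species`` maps species to (max, p95) over its own pairs.
    """

    intra_max: float
    intra_p95: float
    inter_min: float
    inter_max: float
    per_species: Dict[str, Tuple[float, float]]
    species_map: Dict[str, str]

    def to_dict(self) -> dict:
        return {
            "intra_max": self.intra_max,
            "intra_p95": self.intra_p95,
            "inter_min": self.inter_min,
            "inter_max": self.inter_max,
            "per_species": {k: list(v) for k, v in self.per_species.items()},
        }


def read_fasta(source: Union[str, StringIO]) -> Alignment:
    """Read an aligned FASTA file or handle into a normalized Alignment."""
    if isinstance(source, str) and "\n" not in source and source:
        handle = open(source)
    elif isinstance(source, str):
        handle = StringIO(source)
    else:
        handle = source
    records = list(SeqIO.parse(handle, "fasta"))
    if not records:
        raise ValueError("empty FASTA input")
    return Alignment(ids=[r.id for r in records], seqs=[str(r.seq) for r in records])


def collapse_haplotypes(aln: Alignment) -> Tuple[Alignment, Dict[str, List[str]]]:
    """One representative (first occurrence) per distinct sequence string.

    Returns the collapsed alignment and a map from representative id to
    the ids of all members sharing that haplotype.  Idempotent.
    """
    seen: Dict[str, str] = {}
    members: Dict[str, List[str]] = {}
    keep_ids, keep_seqs = [], []
    for rid, s in zip(aln.ids, aln.seqs):
        if s in seen:
            members[seen[s]].append(rid)
        else:
            seen[s] = rid
            members[rid] = [rid]
            keep_ids.append(rid)
            keep_seqs.append(s)
    return Alignment(ids=keep_ids, seqs=keep_seqs), members


def p_distance_matrix(aln: Alignment) -> DistanceMatrix:
    """Pairwise uncorrected p-distances under pairwise deletion."""
    if aln.n < 2:
        raise ValueError("need at least 2 sequences")
    codes = aln.codes()
    valid = codes < 4
    n = aln.n
    values = np.zeros((n, n))
    compared = np.zeros((n, n), dtype=int)
    for i in range(n):
        both = valid[i] & valid[i + 1 :]
        comp = both.sum(axis=1)
        diff = ((codes[i] != codes[i + 1 :]) & both).sum(axis=1)
        with np.errstate(invalid="ignore"):
            d = np.where(comp > 0, diff / np.maximum(comp, 1), np.nan)
        values[i, i + 1 :] = d
        values[i + 1 :, i] = d
        compared[i, i + 1 :] = comp
        compared[i + 1 :, i] = comp
    if np.any(np.isnan(values)):
        warnings.warn("some pairs share no comparable site; distances set to NaN")
    return DistanceMatrix(ids=list(aln.ids), values=values, compared=compared)


def partition_distance_summary(
    dm: DistanceMatrix, species_map: Dict[str, str]
) -> PartitionDistanceSummary:
    """Pool within- and among-species distances given a species partition.

    Every sequence id must be assigned a species; single-member species
    contribute no intra pairs.  NaN pairs are ignored.
    """
    missing = [i for i in dm.ids if i not in species_map]
    if missing:
        raise ValueError(f"sequences without species assignment: {missing}")
    sp = np.array([species_map[i] for i in dm.ids])
    iu, ju = np.triu_indices(len(dm.ids), k=1)
    d = dm.values[iu, ju]
    same = sp[iu] == sp[ju]
    ok = ~np.isnan(d)
    intra = d[same & ok]
    inter = d[~same & ok]
    per_species: Dict[str, Tuple[float, float]] = {}
    for s in sorted(set(sp)):
        mask = same & ok & (sp[iu] == s)
        if np.any(mask):
            vals = d[mask]
            per_species[s] = (float(np.max(vals)), float(np.percentile(vals, 95)))
    return PartitionDistanceSummary(
        intra_max=float(np.max(intra)) if len(intra) else np.nan,
        intra_p95=float(np.percentile(intra, 95)) if len(intra) else np.nan,
        inter_min=float(np.min(inter)) if len(inter) else np.nan,
        inter_max=float(np.max(inter)) if len(inter) else np.nan,
        per_species=per_species,
        species_map=dict(species_map),
    )
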