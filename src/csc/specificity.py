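"""CFD scoring of enumerated sites and per-guide specificity aggregation.

The Cutting Frequency Determination (CFD) score models the chance that Cas9
cleaves a mismatched site as a product of per-position, per-identity mismatch
penalties times a PAM penalty.  A guide's aggregate specificity is

    s = 1 / sum_over_enumerated_sites CFD(site)

computed over its complete Hamming<=3 neighborhood: a guide whose only site
is its single perfect target (CFD 1) scores s = 1, and s tends to 0 as
off-target CFD mass accumulates.  Guides with no perfect target (H0 = 0)
have no defined score and are flagged instead.

Penalty positions are numbered 1..20 reading 5'->3' along the protospacer,
so position 20 abuts the PAM.  19-mer guides are scored by anchoring to the
PAM-proximal positions 2..20 of the 20-position table.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .genome_index import NeighborCounts, TargetIndex, TargetSite

__all__ = [
    "CFDPenaltyTable",
    "SpecificityProfile",
    "cfd",
    "specificity_score",
    "annotate_library",
    "load_cfd_table",
    "synthetic_cfd_table",
]

FLAG_NO_PERFECT_TARGET = "no_perfect_target"
FLAG_NOT_IN_INDEX = "not_in_index"

_NGG_PAMS = ("AGG", "CGG", "GGG", "TGG")


@dataclass(frozen=True)
class CFDPenaltyTable:
    """Mismatch penalties keyed by (position 1..20, guide base, site base)
    plus PAM penalties keyed by the full 3-mer PAM."""

    mismatch_penalty: Mapping[tuple[int, str, str], float]
    pam_penalty: Mapping[str, float]

    def __post_init__(self):
        for key, v in self.mismatch_penalty.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"mismatch penalty out of [0,1] at {key}: {v}")
        for pam, v in self.pam_penalty.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"PAM penalty out of [0,1] for {pam}: {v}")
        for pam in _NGG_PAMS:
            if pam in self.pam_penalty and self.pam_penalty[pam] != 1.0:
                raise ValueError(f"NGG PAM penalty must be 1, got "
                                 f"{self.pam_penalty[pam]} for {pam}")

    def mismatch(self, position: int, guide_base: str, site_base: str) -> float:
        try:
            return self.mismatch_penalty[(position, guide_base, site_base)]
        except KeyError:
            raise KeyError(
                f"no CFD penalty for position {position} "
                f"{guide_base}->{site_base}") from None

    def pam(self, pam: str) -> float:
        try:
            return self.pam_penalty[pam]
        except KeyError:
            raise KeyError(f"no CFD penalty for PAM {pam!r}") from None

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "CFDPenaltyTable":
        mm = {}
        pam = {}
        for row in df.itertuples(index=False):
            if row.kind == "mismatch":
                mm[(int(row.position), row.guide_base, row.site_base)] = float(row.penalty)
            elif row.kind == "pam":
                pam[row.pam] = float(row.penalty)
            else:
                raise ValueError(f"unknown CFD table row kind {row.kind!r}")
        return cls(mm, pam)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"kind": "mismatch", "position": p, "guide_base": g,
             "site_base": s, "pam": "", "penalty": v}
            for (p, g, s), v in sorted(self.mismatch_penalty.items())
        ] + [
            {"kind": "pam", "position": 0, "guide_base": "", "site_base": "",
             "pam": p, "penalty": v}
            for p, v in sorted(self.pam_penalty.items())
        ]
        return pd.DataFrame(rows)


def synthetic_cfd_table() -> CFDPenaltyTable:
    """Deterministic synthetic stand-in for the published CFD constants.

    This is NOT the empirical CFD table: it is a stand-in built from the
    qualitative structure of Cas9 mismatch tolerance — penalties shrink
    toward the PAM-proximal seed, and transition-like mismatches are more
    tolerated than transversions.  It exists so the package is fully
    exercisable without the proprietary-licensed empirical constants; users
    with the real table can load it with :func:`load_cfd_table`.
    """
    transitions = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}
    mm = {}
    for pos in range(1, 21):
        # tolerance decays linearly 5' -> PAM: 0.95 at position 1, 0.10 at 20
        base = 0.95 - 0.85 * (pos - 1) / 19
        for g in "ACGT":
            for s in "ACGT":
                if g == s:
                    continue
                factor = 1.15 if (g, s) in transitions else 0.8
                mm[(pos, g, s)] = round(min(1.0, max(0.02, base * factor)), 4)
    pam = {}
    for n in "ACGT":
        pam[n + "AG"] = 0.25
        pam[n + "GA"] = 0.05
    for p in _NGG_PAMS:
        pam[p] = 1.0
    return CFDPenaltyTable(mm, pam)


def load_cfd_table(path: str | Path | None = None) -> CFDPenaltyTable:
    """Load a CFD penalty table from TSV; defaults to the packaged synthetic
    stand-in table."""
    if path is None:
        ref = resources.files("csc.data").joinpath("cfd_table_synthetic.tsv")
        with resources.as_file(ref) as p:
            df = pd.read_csv(p, sep="\t", keep_default_na=False)
    else:
        df = pd.read_csv(path, sep="\t", keep_default_na=False)
    return CFDPenaltyTable.from_frame(df)


def cfd(guide: str, site: TargetSite, table: CFDPenaltyTable) -> float:
    """CFD of a site: product of mismatch penalties times the PAM penalty.

    A perfect match with an NGG PAM returns 1 (empty product).  19-mer
    guides anchor to table positions 2..20.
    """
    guide = guide.upper()
    proto = site.protospacer.upper()
    if len(guide) != len(proto):
        raise ValueError(
            f"guide length {len(guide)} != site protospacer length {len(proto)}")
    offset = 20 - len(guide)
    if offset not in (0, 1):
        raise ValueError(f"guide length must be 19 or 20, got {len(guide)}")
    value = table.pam(site.pam.upper())
    for i, (g, s) in enumerate(zip(guide, proto)):
        if g != s:
            value *= table.mismatch(i + 1 + offset, g, s)
    return value


def specificity_score(sites_with_cfd: Iterable[tuple[TargetSite, float]]):
    """Aggregate s = 1 / sum(CFD) over a guide's complete enumeration.

    Returns (score, flags).  With no perfect (distance-0) site the score is
    undefined (NaN) and ``no_perfect_target`` is flagged; it never defaults
    to 0, which would fake maximal promiscuity.
    """
    pairs = list(sites_with_cfd)
    flags: list[str] = []
    if not any(site.distance == 0 for site, _ in pairs):
        flags.append(FLAG_NO_PERFECT_TARGET)
        if not pairs:
            flags.append(FLAG_NOT_IN_INDEX)
        return float("nan"), flags
    total = sum(v for _, v in pairs)
    return 1.0 / total, flags


@dataclass(frozen=True)
class SpecificityProfile:
    """Per-guide neighborhood summary: the five model covariates
    (s, H0, H1, H2, H3) plus flags."""

    guide_id: str
    sequence: str
    gene: str
    counts: NeighborCounts
    score: float
    flags: tuple[str, ...] = ()

    @property
    def covariates(self) -> tuple[float, int, int, int, int]:
        return (self.score, self.counts.H0, self.counts.H1,
                self.counts.H2, self.counts.H3)


def profile_guide(index: TargetIndex, guide_id: str, sequence: str,
                  table: CFDPenaltyTable, gene: str = "") -> SpecificityProfile:
    sites = index.query(sequence, max_distance=3)
    pairs = [(s, cfd(sequence, s, table)) for s in sites]
    score, flags = specificity_score(pairs)
    counts = index.neighbor_counts(sequence, max_distance=3)
    return SpecificityProfile(guide_id, sequence.upper(), gene, counts,
                              score, tuple(flags))


def annotate_library(index: TargetIndex, guides: pd.DataFrame,
                     table: CFDPenaltyTable) -> pd.DataFrame:
    """Annotate a guide library with H0..H3 and the specificity score.

    ``guides`` needs columns guide_id and sequence (gene optional).  Guides
    absent from the genome are flagged, never dropped.  Output columns:
    guide_id, sequence, gene, H0, H1, H2, H3, specificity, flags.
    """
    required = {"guide_id", "sequence"}
    missing = required - set(guides.columns)
    if missing:
        raise ValueError(f"library table missing columns: {sorted(missing)}")
    if guides["guide_id"].duplicated().any():
        dups = guides.loc[guides["guide_id"].duplicated(), "guide_id"].tolist()
        raise ValueError(f"duplicate guide IDs: {dups[:5]}")

    # score each unique sequence once; libraries repeat sequences rarely but
    # synthetic ones may
    uniq: dict[str, tuple] = {}
    for seq in pd.unique(guides["sequence"]):
        s = str(seq).upper()
        sites = index.query(s, max_distance=3)
        pairs = [(t, cfd(s, t, table)) for t in sites]
        score, flags = specificity_score(pairs)
        h = [0, 0, 0, 0]
        for t in sites:
            h[t.distance] += 1
        uniq[str(seq)] = (h, score, ";".join(flags))

    rows = []
    for row in guides.itertuples(index=False):
        h, score, flags = uniq[str(row.sequence)]
        rows.append({
            "guide_id": row.guide_id,
            "sequence": str(row.sequence).upper(),
            "gene": getattr(row, "gene", ""),
            "H0": h[0], "H1": h[1], "H2": h[2], "H3": h[3],
            "specificity": score,
            "flags": flags,
        })
    return pd.DataFrame(rows)
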