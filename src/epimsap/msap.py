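"""MSAP band classification and methylation summary statistics.

MSAP (methylation-sensitive amplified polymorphism) profiles a genome at
CCGG restriction sites using the isoschizomers HpaII and MspI, which differ
in their sensitivity to cytosine methylation.  Each locus in each individual
is represented by a pair of presence/absence bands, one from the
EcoRI/HpaII digest and one from the EcoRI/MspI digest.  The four possible
band patterns are interpreted as:

========  ==========  =======================================
(H, M)    state       interpretation at the CCGG site
========  ==========  =======================================
(1, 1)    TYPE_I      unmethylated
(1, 0)    TYPE_II     hemimethylated (one strand)
(0, 1)    TYPE_III    internal cytosine methylated, both strands
(0, 0)    TYPE_IV     fully methylated (all four cytosines)
========  ==========  =======================================

The module converts band-pair tables into a four-state epigenotype matrix,
computes the standard methylated-cytosine percentage

    %mC = 100 * (2*nII + 2*nIII + 4*nIV) / (4 * (nI + nII + nIII + nIV))

(each CCGG site samples four cytosines; hemimethylated and internal-CG
states contribute two methylated cytosines, the fully methylated state
four), partitions methylated loci into hemi/internal/full fractions,
selects methylation-susceptible loci (MSL), and checks genetic uniformity
of ordinary presence/absence (AFLP-style) band tables.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MethylationState",
    "TypeCounts",
    "MSAPMatrix",
    "MSLPartition",
    "classify_band_pair",
    "state_to_bands",
    "methylated_cytosine_percent",
    "methylation_partition",
    "unmethylated_percent",
    "select_msl",
    "check_uniformity",
    "round_half_up",
]

MISSING = -1  # internal code for a missing call


class MethylationState(enum.IntEnum):
    """Four-state methylation call for one CCGG locus in one individual."""

    TYPE_I = 1  # (1,1) unmethylated
    TYPE_II = 2  # (1,0) hemimethylated
    TYPE_III = 3  # (0,1) internal-CG methylated
    TYPE_IV = 4  # (0,0) fully methylated


#: states counted as "methylated" for summary statistics and MSL selection
METHYLATED_STATES = (
    MethylationState.TYPE_II,
    MethylationState.TYPE_III,
    MethylationState.TYPE_IV,
)

_BANDS_TO_STATE = {
    (1, 1): MethylationState.TYPE_I,
    (1, 0): MethylationState.TYPE_II,
    (0, 1): MethylationState.TYPE_III,
    (0, 0): MethylationState.TYPE_IV,
}
_STATE_TO_BANDS = {v: k for k, v in _BANDS_TO_STATE.items()}


def classify_band_pair(hpa_present: int, msp_present: int) -> MethylationState:
    """Classify one (HpaII, MspI) presence/absence pair into a methylation state.

    Parameters
    ----------
    hpa_present, msp_present : int
        Presence (1) or absence (0) of the band in the EcoRI/HpaII and
        EcoRI/MspI digest lanes respectively.
    """
    for name, v in (("hpa_present", hpa_present), ("msp_present", msp_present)):
        if v not in (0, 1):
            raise ValueError(f"{name} must be 0 or 1, got {v!r}")
    return _BANDS_TO_STATE[(int(hpa_present), int(msp_present))]


def state_to_bands(state: MethylationState) -> tuple[int, int]:
    """Inverse of :func:`classify_band_pair`."""
    return _STATE_TO_BANDS[MethylationState(state)]


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Round with ties away from zero (presentation only)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class TypeCounts:
    """Counts of loci per MSAP band type (I/II/III/IV)."""

    n_I: int
    n_II: int
    n_III: int
    n_IV: int

    def __post_init__(self) -> None:
        for name in ("n_I", "n_II", "n_III", "n_IV"):
            v = getattr(self, name)
            if v < 0 or int(v) != v:
                raise ValueError(f"{name} must be a non-negative integer, got {v!r}")

    @property
    def total(self) -> int:
        return self.n_I + self.n_II + self.n_III + self.n_IV

    @property
    def n_methylated(self) -> int:
        return self.n_II + self.n_III + self.n_IV

    def as_tuple(self) -> tuple[int, int, int, int]:
        return (self.n_I, self.n_II, self.n_III, self.n_IV)


def methylated_cytosine_percent(counts: TypeCounts) -> float:
    """Percentage of methylated cytosines among those sampled by the CCGG sites.

    Each site samples four cytosines (two per strand); type II and III sites
    carry two methylated cytosines, type IV sites four:

        100 * (2*nII + 2*nIII + 4*nIV) / (4 * total)
    """
    if counts.total == 0:
        raise ValueError("cannot compute a percentage from zero loci")
    num = 2 * counts.n_II + 2 * counts.n_III + 4 * counts.n_IV
    return 100.0 * num / (4 * counts.total)


def unmethylated_percent(counts: TypeCounts) -> float:
    """Percentage of sampled cytosines lacking a methyl group."""
    return 100.0 - methylated_cytosine_percent(counts)


def methylation_partition(counts: TypeCounts) -> tuple[float, float, float]:
    """Partition methylated loci into (hemi, internal, full) percentages.

    The denominator is the number of methylated loci m = nII + nIII + nIV;
    the three components sum to 100 (up to rounding).
    """
    m = counts.n_methylated
    if m == 0:
        raise ValueError("no methylated loci; partition undefined")
    return (100.0 * counts.n_II / m, 100.0 * counts.n_III / m, 100.0 * counts.n_IV / m)


@dataclass
class MSAPMatrix:
    """Four-state epigenotype matrix: individuals x loci.

    ``calls`` holds :class:`MethylationState` integer codes with ``-1`` for
    missing cells.  ``groups`` carries one label per individual (dose class,
    phenotype class, ...).
    """

    individuals: list[str]
    groups: list[str]
    loci: list[str]
    calls: np.ndarray  # int8, shape (n_individuals, n_loci), -1 = missing

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        n, L = len(self.individuals), len(self.loci)
        if self.calls.shape != (n, L):
            raise ValueError(
                f"calls shape {self.calls.shape} does not match "
                f"{n} individuals x {L} loci"
            )
        if len(self.groups) != n:
            raise ValueError("one group label required per individual")
        valid = np.isin(self.calls, [MISSING, 1, 2, 3, 4])
        if not valid.all():
            bad = sorted(set(self.calls[~valid].tolist()))
            raise ValueError(f"invalid state codes in calls: {bad}")

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    def group_labels(self) -> list[str]:
        """Distinct group labels in first-appearance order."""
        seen: dict[str, None] = {}
        for g in self.groups:
            seen.setdefault(g, None)
        return list(seen)

    def type_counts(self, group: str | None = None) -> TypeCounts:
        """Pooled band-type counts over all non-missing cells (optionally one group)."""
        calls = self.calls
        if group is not None:
            mask = np.asarray([g == group for g in self.groups])
            if not mask.any():
                raise KeyError(f"unknown group {group!r}")
            calls = calls[mask]
        flat = calls[calls != MISSING]
        return TypeCounts(*(int((flat == s).sum()) for s in MethylationState))

    def to_frame(self) -> pd.DataFrame:
        """Calls as a DataFrame of state names (NaN for missing) plus a group column."""
        names = {s.value: s.name for s in MethylationState}
        data = [[names.get(int(c), None) for c in row] for row in self.calls]
        df = pd.DataFrame(data, index=self.individuals, columns=self.loci)
        df.insert(0, "group", self.groups)
        df.index.name = "individual"
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "MSAPMatrix":
        """Inverse of :meth:`to_frame`."""
        if "group" not in df.columns:
            raise ValueError("state table requires a 'group' column")
        groups = df["group"].astype(str).tolist()
        body = df.drop(columns=["group"])
        codes = {s.name: s.value for s in MethylationState}
        calls = np.full(body.shape, MISSING, dtype=np.int8)
        for j, col in enumerate(body.columns):
            for i, v in enumerate(body[col]):
                if isinstance(v, str) and v:
                    calls[i, j] = codes[v]
        return cls(
            individuals=[str(i) for i in body.index],
            groups=groups,
            loci=[str(c) for c in body.columns],
            calls=calls,
        )


@dataclass(frozen=True)
class MSLPartition:
    """Partition of loci into methylation-susceptible (MSL) and non-MSL (NML)."""

    msl: frozenset[str]
    polymorphic_msl: frozenset[str]
    nml: frozenset[str]

    def __post_init__(self) -> None:
        if not self.polymorphic_msl <= self.msl:
            raise ValueError("polymorphic MSL must be a subset of MSL")
        if self.msl & self.nml:
            raise ValueError("MSL and NML overlap")


def select_msl(
    matrix: MSAPMatrix,
    min_methylated_fraction: float = 0.05,
    min_unmethylated_individuals: int = 2,
    type_iv_as_missing: bool = False,
) -> MSLPartition:
    """Select methylation-susceptible loci (MSL).

    A locus is MSL when the fraction of (non-missing) individuals carrying a
    methylated state (type II/III/IV) is at least ``min_methylated_fraction``;
    an MSL is polymorphic when at least ``min_unmethylated_individuals``
    individuals carry the unmethylated type I state.

    ``type_iv_as_missing`` treats the absent/absent pattern as uninformative
    (it can also reflect restriction-site loss) and drops it from both the
    numerator and the denominator.
    """
    if matrix.n_individuals == 0 or matrix.n_loci == 0:
        raise ValueError("empty matrix")
    if not (0.0 <= min_methylated_fraction <= 1.0):
        raise ValueError("min_methylated_fraction must be in [0, 1]")
    calls = matrix.calls
    missing = calls == MISSING
    if type_iv_as_missing:
        missing = missing | (calls == MethylationState.TYPE_IV)
    methylated = np.isin(calls, [s.value for s in METHYLATED_STATES]) & ~missing
    unmeth = (calls == MethylationState.TYPE_I) & ~missing
    n_valid = (~missing).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(n_valid > 0, methylated.sum(axis=0) / np.maximum(n_valid, 1), 0.0)
    is_msl = (n_valid > 0) & (frac >= min_methylated_fraction)
    is_poly = is_msl & (unmeth.sum(axis=0) >= min_unmethylated_individuals)
    loci = np.asarray(matrix.loci, dtype=object)
    return MSLPartition(
        msl=frozenset(loci[is_msl]),
        polymorphic_msl=frozenset(loci[is_poly]),
        nml=frozenset(loci[~is_msl]),
    )


def check_uniformity(
    band_matrix: pd.DataFrame | np.ndarray,
    loci: Sequence[str] | None = None,
) -> tuple[bool, list[str]]:
    """Check that every locus column of a presence/absence matrix is constant.

    Returns ``(uniform, polymorphic_loci)``; used to verify genetic
    uniformity of AFLP profiles across individuals.
    """
    if isinstance(band_matrix, pd.DataFrame):
        cols = [c for c in band_matrix.columns if c != "group"]
        values = band_matrix[cols].to_numpy()
        names = [str(c) for c in cols]
    else:
        values = np.asarray(band_matrix)
        names = [str(l) for l in loci] if loci is not None else [
            f"L{j}" for j in range(values.shape[1] if values.ndim == 2 else 0)
        ]
    if values.size == 0:
        raise ValueError("empty band matrix")
    constant = (values == values[0]).all(axis=0)
    polymorphic = [names[j] for j in np.flatnonzero(~constant)]
    return (len(polymorphic) == 0, polymorphic)
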