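"""Stable-isotope arithmetic for carbon: delta notation, ratios, atom fractions.

Carbon isotope measurements come in three mutually convertible currencies:

* the isotope ratio ``R = 13C / 12C``,
* the atom fraction ``x = 13C / (12C + 13C)`` (what mixing models need),
* delta notation ``delta13C = (R_sample / R_standard - 1) * 1000`` in permil
  relative to an agreed reference standard (VPDB for carbon).

Mixing of DNA pools is linear in atom fraction, not in delta, so every
quantitative operation here converts to atom-fraction space first.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy import stats

from ._stats import permutation_t_pvalue

__all__ = [
    "ReferenceStandard",
    "IsotopeMeasurement",
    "VPDB",
    "delta_from_ratio",
    "ratio_from_delta",
    "atom_fraction_from_ratio",
    "ratio_from_atom_fraction",
    "atom_fraction_from_delta",
    "delta_from_atom_fraction",
    "excess_atom_fraction",
    "mixing_fraction",
    "compare_delta_groups",
]


@dataclass(frozen=True)
class ReferenceStandard:
    """An isotope reference standard defined by its 13C/12C ratio.

    The default VPDB ratio (0.0111802) is one of two circulating conventions
    (the other being 0.011237); it is exposed here rather than hard-wired so a
    laboratory's preferred value can be substituted.
    """

    name: str = "VPDB"
    ratio: float = 0.0111802

    def __post_init__(self) -> None:
        if not self.ratio > 0:
            raise ValueError(f"reference ratio must be > 0, got {self.ratio}")


#: Vienna Pee Dee Belemnite, the international carbon reference.
VPDB = ReferenceStandard()


@dataclass(frozen=True)
class IsotopeMeasurement:
    """A 13C measurement carried in all three representations at once.

    Attributes
    ----------
    delta : float
        delta13C in permil vs. the standard.
    ratio : float
        13C/12C isotope ratio.
    atom_fraction : float
        13C/(12C+13C), in [0, 1].
    sd : float or None
        Optional standard deviation of the delta value, permil.
    standard : ReferenceStandard
        The reference the delta value is anchored to.
    """

    delta: float
    ratio: float
    atom_fraction: float
    sd: float | None = None
    standard: ReferenceStandard = VPDB

    @classmethod
    def from_delta(
        cls, delta: float, sd: float | None = None, std: ReferenceStandard = VPDB
    ) -> "IsotopeMeasurement":
        r = ratio_from_delta(delta, std)
        return cls(delta=delta, ratio=r, atom_fraction=atom_fraction_from_ratio(r), sd=sd, standard=std)

    @classmethod
    def from_atom_fraction(
        cls, af: float, sd: float | None = None, std: ReferenceStandard = VPDB
    ) -> "IsotopeMeasurement":
        r = ratio_from_atom_fraction(af)
        return cls(delta=delta_from_ratio(r, std), ratio=r, atom_fraction=af, sd=sd, standard=std)


def delta_from_ratio(r_sample: float, std: ReferenceStandard = VPDB) -> float:
    """delta13C (permil) of a sample with isotope ratio ``r_sample``."""
    if r_sample < 0:
        raise ValueError(f"isotope ratio must be >= 0, got {r_sample}")
    return (r_sample / std.ratio - 1.0) * 1000.0


def ratio_from_delta(delta: float, std: ReferenceStandard = VPDB) -> float:
    """Isotope ratio of a sample with the given delta13C (permil)."""
    return delta / 1000.0 * std.ratio + std.ratio


def atom_fraction_from_ratio(r: float) -> float:
    """13C atom fraction from the 13C/12C ratio."""
    if r < 0:
        raise ValueError(f"isotope ratio must be >= 0, got {r}")
    return r / (1.0 + r)


def ratio_from_atom_fraction(af: float) -> float:
    """13C/12C ratio from the atom fraction; undefined at af = 1."""
    if not 0.0 <= af < 1.0:
        raise ValueError(f"atom fraction must be in [0, 1), got {af}")
    return af / (1.0 - af)


def atom_fraction_from_delta(delta: float, std: ReferenceStandard = VPDB) -> float:
    return atom_fraction_from_ratio(ratio_from_delta(delta, std))


def delta_from_atom_fraction(af: float, std: ReferenceStandard = VPDB) -> float:
    return delta_from_ratio(ratio_from_atom_fraction(af), std)


def excess_atom_fraction(
    delta_labeled: float, delta_control: float, std: ReferenceStandard = VPDB
) -> float:
    """Atom-fraction excess of a labeled sample over an unlabeled control.

    Positive iff ``delta_labeled > delta_control``; this is the quantity
    ("atom percent excess" when multiplied by 100) that scales linearly with
    the amount of label incorporated.
    """
    return atom_fraction_from_delta(delta_labeled, std) - atom_fraction_from_delta(
        delta_control, std
    )


@dataclass(frozen=True)
class MixingEstimate:
    """Result of the two-pool mixing model.

    ``fraction`` is the share of carbon drawn from the labeled pool. Values
    outside [0, 1] are returned as-is with ``in_range=False`` so the caller
    can see that the model assumptions were violated, rather than being
    silently clamped.
    """

    fraction: float
    in_range: bool


def mixing_fraction(
    delta_bulk: float,
    delta_unlabeled: float,
    af_label_pool: float,
    std: ReferenceStandard = VPDB,
) -> MixingEstimate:
    """Two-pool isotope mixing: fraction of carbon from the labeled pool.

    Solves ``x_bulk = f * x_label + (1 - f) * x_unlabeled`` for ``f`` in
    atom-fraction space. Delta-space mixing is only approximately linear and
    breaks down when the labeled pool is far from natural abundance, hence the
    conversion.
    """
    x_bulk = atom_fraction_from_delta(delta_bulk, std)
    x_un = atom_fraction_from_delta(delta_unlabeled, std)
    if not af_label_pool > x_un:
        raise ValueError(
            "labeled-pool atom fraction must exceed the unlabeled baseline "
            f"({af_label_pool} <= {x_un}); the mixing model is degenerate"
        )
    f = (x_bulk - x_un) / (af_label_pool - x_un)
    return MixingEstimate(fraction=f, in_range=0.0 <= f <= 1.0)


def compare_delta_groups(
    labeled: Sequence[float],
    control: Sequence[float],
    method: Literal["auto", "welch", "permutation"] = "auto",
    equal_var: bool = False,
    max_exact: int = 10_000,
) -> float:
    """Two-sided p-value for a difference in delta13C between two groups.

    ``method="welch"`` runs a t-test (Welch by default; ``equal_var=True``
    gives the pooled-variance Student variant). ``method="permutation"``
    enumerates all distinct group assignments when there are at most
    ``max_exact`` of them, using |t| as the statistic, and is preferred for
    the tiny replicate numbers typical of IRMS work. ``"auto"`` picks the
    exact permutation test when enumeration is feasible, Welch otherwise.
    """
    x = np.asarray(labeled, dtype=float)
    y = np.asarray(control, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("need at least 2 values per group")
    n_splits = math.comb(x.size + y.size, x.size)
    if method == "auto":
        method = "permutation" if n_splits <= max_exact else "welch"
    if method == "permutation":
        if n_splits > max_exact:
            raise ValueError(
                f"{n_splits} distinct splits exceed max_exact={max_exact}; use method='welch'"
            )
        return permutation_t_pvalue(x, y)
    pooled = np.concatenate([x, y])
    if np.ptp(pooled) == 0:  # all values identical: no evidence of difference
        return 1.0
    res = stats.ttest_ind(x, y, equal_var=equal_var)
    return float(res.pvalue)
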