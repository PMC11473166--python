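"""Observed/expected zone agreement — the central quantification.

The obs/exp ratio of a zone is the fraction of spots expected in that zone
whose observed (expression-derived) label matches; the overall ratio pools
matches and denominators across zones. Spots with expected zone ``none`` are
excluded from every denominator, and an observed ``none`` counts as a
mismatch (conservative). A permutation null — shuffling observed labels among
the scored spots — attaches a significance level to the overall ratio.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .errors import IncomparableRunsError, InvalidConfigurationError, UndefinedAgreementError
from .lesions import ExpectedZoneMap
from .panel import ZONES


@dataclasses.dataclass(frozen=True)
class ZoneAgreement:
    """Per-zone and overall observed/expected agreement.

    ``per_zone`` is indexed by zone with columns ``n_expected``, ``n_match``
    and ``ratio`` (NaN when ``n_expected`` is 0 — reported missing, never
    0/0). ``overall_ratio`` = sum(n_match) / sum(n_expected) over all zones.
    """

    per_zone: pd.DataFrame
    overall_ratio: float
    n_spots_scored: int
    w_B_um: float
    w_C_um: float

    def ratio(self, zone: str) -> float:
        return float(self.per_zone.loc[zone, "ratio"])

    def to_dict(self) -> dict:
        return {
            "per_zone": {
                z: {
                    "n_expected": int(self.per_zone.loc[z, "n_expected"]),
                    "n_match": int(self.per_zone.loc[z, "n_match"]),
                    "ratio": (
                        None
                        if pd.isna(self.per_zone.loc[z, "ratio"])
                        else float(self.per_zone.loc[z, "ratio"])
                    ),
                }
                for z in ZONES
            },
            "overall_ratio": self.overall_ratio,
            "n_spots_scored": self.n_spots_scored,
            "w_B_um": self.w_B_um,
            "w_C_um": self.w_C_um,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ZoneAgreement":
        per_zone = pd.DataFrame(
            {
                "n_expected": [d["per_zone"][z]["n_expected"] for z in ZONES],
                "n_match": [d["per_zone"][z]["n_match"] for z in ZONES],
                "ratio": [
                    np.nan if d["per_zone"][z]["ratio"] is None else d["per_zone"][z]["ratio"]
                    for z in ZONES
                ],
            },
            index=pd.Index(ZONES, name="zone"),
        )
        return cls(
            per_zone=per_zone,
            overall_ratio=float(d["overall_ratio"]),
            n_spots_scored=int(d["n_spots_scored"]),
            w_B_um=float(d["w_B_um"]),
            w_C_um=float(d["w_C_um"]),
        )


def _aligned_labels(
    expected: ExpectedZoneMap, observed: pd.Series
) -> tuple[np.ndarray, np.ndarray, pd.Index]:
    exp = expected.zones
    if not exp.index.sort_values().equals(observed.index.sort_values()):
        raise InvalidConfigurationError(
            "expected and observed zone maps must cover the same spots"
        )
    obs = observed.reindex(exp.index)
    return exp.to_numpy(object), obs.to_numpy(object), exp.index


def agreement_ratio(
    expected: ExpectedZoneMap,
    observed: pd.Series,
    exclude_edge: bool = False,
) -> ZoneAgreement:
    """Per-zone and overall obs/exp ratios.

    ``observed`` maps spot id -> zone label in {A, B, C, none}. With
    ``exclude_edge``, spots flagged as edge-proximal are removed from every
    denominator. Raises :class:`UndefinedAgreementError` when no spot has an
    expected zone in {A, B, C}.
    """
    exp, obs, index = _aligned_labels(expected, observed)
    scored = np.isin(exp, ZONES)
    if exclude_edge:
        scored &= ~expected.frame["edge"].to_numpy(bool)
    if not scored.any():
        raise UndefinedAgreementError(
            "no spot has an expected zone in {A, B, C}; agreement is undefined"
        )
    rows = []
    for z in ZONES:
        mask = scored & (exp == z)
        n_exp = int(mask.sum())
        n_match = int((obs[mask] == z).sum())
        rows.append(
            {
                "n_expected": n_exp,
                "n_match": n_match,
                "ratio": (n_match / n_exp) if n_exp > 0 else np.nan,
            }
        )
    per_zone = pd.DataFrame(rows, index=pd.Index(ZONES, name="zone"))
    total_exp = int(per_zone["n_expected"].sum())
    overall = float(per_zone["n_match"].sum() / total_exp)
    return ZoneAgreement(
        per_zone=per_zone,
        overall_ratio=overall,
        n_spots_scored=int(scored.sum()),
        w_B_um=expected.w_B_um,
        w_C_um=expected.w_C_um,
    )


@dataclasses.dataclass(frozen=True)
class AgreementNull:
    """Permutation null of the overall obs/exp ratio."""

    observed_ratio: float
    null_ratios: np.ndarray
    p_value: float
    n_perm: int


def agreement_null(
    expected: ExpectedZoneMap,
    observed: pd.Series,
    n_perm: int = 1000,
    seed: int = 0,
    exclude_edge: bool = False,
) -> AgreementNull:
    """One-sided permutation test of the overall agreement ratio.

    Observed labels are permuted uniformly among the scored spots (those with
    expected zone in {A, B, C}) ``n_perm`` times; each permutation preserves
    the multiset of observed labels. ``p = (1 + #{null >= observed}) /
    (n_perm + 1)``.
    """
    base = agreement_ratio(expected, observed, exclude_edge=exclude_edge)
    exp, obs, _ = _aligned_labels(expected, observed)
    scored = np.isin(exp, ZONES)
    if exclude_edge:
        scored &= ~expected.frame["edge"].to_numpy(bool)
    exp_s = exp[scored]
    obs_s = obs[scored]
    n_exp_total = int(np.isin(exp_s, ZONES).sum())

    rng = np.random.default_rng(seed)
    null = np.empty(n_perm, dtype=float)
    for i in range(n_perm):
        perm = rng.permutation(obs_s)
        null[i] = float((perm == exp_s).sum()) / n_exp_total
    p = (1.0 + float(np.sum(null >= base.overall_ratio))) / (n_perm + 1.0)
    return AgreementNull(
        observed_ratio=base.overall_ratio, null_ratios=null, p_value=p, n_perm=n_perm
    )


@dataclasses.dataclass(frozen=True)
class CollapseReport:
    """Per-zone agreement differences between two runs (b minus a)."""

    delta_ratio: pd.Series
    collapse_flags: dict[str, bool]
    collapse_threshold: float

    def to_dict(self) -> dict:
        return {
            "delta_ratio": {
                z: (None if pd.isna(v) else float(v)) for z, v in self.delta_ratio.items()
            },
            "collapse_flags": dict(self.collapse_flags),
            "collapse_threshold": self.collapse_threshold,
        }


def zone_collapse_report(
    agreement_a: ZoneAgreement,
    agreement_b: ZoneAgreement,
    collapse_threshold: float = 0.05,
) -> CollapseReport:
    """Compare two agreements (same widths/panel): delta ratios and flags.

    Zone ``z`` is flagged collapsed when its ratio in run *b* drops to
    ``collapse_threshold`` or below while run *a* held at 0.5 or above —
    e.g. the loss of the regenerating periphery (zone C) under glucocorticoid
    treatment. Runs produced under different zone widths raise
    :class:`IncomparableRunsError`.
    """
    if (agreement_a.w_B_um, agreement_a.w_C_um) != (agreement_b.w_B_um, agreement_b.w_C_um):
        raise IncomparableRunsError(
            "agreements computed with different zone widths are not comparable: "
            f"({agreement_a.w_B_um}, {agreement_a.w_C_um}) vs "
            f"({agreement_b.w_B_um}, {agreement_b.w_C_um})"
        )
    delta = agreement_b.per_zone["ratio"] - agreement_a.per_zone["ratio"]
    flags = {}
    for z in ZONES:
        ra = agreement_a.per_zone.loc[z, "ratio"]
        rb = agreement_b.per_zone.loc[z, "ratio"]
        flags[z] = bool(
            pd.notna(ra) and pd.notna(rb) and rb <= collapse_threshold and ra >= 0.5
        )
    return CollapseReport(
        delta_ratio=delta.rename("delta_ratio"),
        collapse_flags=flags,
        collapse_threshold=float(collapse_threshold),
    )
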