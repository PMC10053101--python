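"""Isozyme partitioning and inhibitor-based fractionation.

Two procedures separate the contribution of one alkaline-phosphatase (AP)
isozyme from a mixture:

* **Lysate partitioning** — a recombinant isoform expressed in a host lysate is
  assayed as *total* activity, the vector-only lysate as *background*; the
  isoform-specific signal is the difference.  Vmax partitions exactly as a
  parameter difference; the isoform-specific Km is obtained by fitting the
  point-wise difference curve (which is not exactly Michaelis–Menten, so both
  routes are provided and labelled).
* **Inhibitor fractionation** — L-phenylalanine selectively inhibits
  intestinal-type AP (IAP) and L-homoarginine the tissue-nonspecific isoform
  (TNAP); residual activities at graded inhibitor concentrations, normalized
  to the no-inhibitor (0 mM) baseline, classify which isoform family dominates
  a tissue segment.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd

from .core_io import (
    DomainError,
    GridMismatchError,
    KineticDataset,
    SchemaError,
)
from .kinetic_models import MMParams

INHIBITORS = ("L-Phe", "L-hArg")
DOMINANCE_THRESHOLD = 50.0  # percent inhibition at the top concentration


class Dominance(str, Enum):
    IAP = "IAP-dominant"
    TNAP = "TNAP-dominant"
    MIXED = "mixed"


@dataclass(frozen=True)
class PartitionedVmax:
    """Parameter-difference Vmax with quadrature-propagated SE."""

    Vmax: float
    se: float


@dataclass(frozen=True)
class PartitionedKinetics:
    total: MMParams
    background: MMParams
    specific: MMParams
    method: str  # "pointwise" | "parameter_difference"

    def __post_init__(self):
        if self.method not in ("pointwise", "parameter_difference"):
            raise SchemaError(f"unknown partition method {self.method!r}")


# ---------------------------------------------------------------------------
# lysate partitioning
# ---------------------------------------------------------------------------


def partition_pointwise(
    total: KineticDataset, background: KineticDataset
) -> KineticDataset:
    """Per-concentration activity difference (total − background).

    Both datasets must share the substrate grid after sorting.  Negative
    differences are preserved (clipping would bias the downstream fit) and
    reported with a warning.
    """
    st = np.sort(np.unique(total.substrate))
    sb = np.sort(np.unique(background.substrate))
    if len(st) != len(sb) or not np.allclose(st, sb):
        unmatched = sorted(set(st.tolist()) ^ set(sb.tolist()))
        raise GridMismatchError(
            f"substrate grids differ at concentrations {unmatched}",
            unmatched=unmatched,
        )
    # average replicates per level on each side, subtract level-wise
    mt = total.level_means()
    mb = background.level_means()
    diff = mt.velocity - mb.velocity
    if np.any(diff < 0):
        warnings.warn(
            f"{int(np.sum(diff < 0))} negative point-wise difference(s) "
            "retained (not clipped)",
            stacklevel=2,
        )
    return KineticDataset.from_arrays(
        mt.substrate, diff, unit="uM",
        specimen_id="partitioned", condition="total-minus-background",
    )


def partition_parameters(total: MMParams, background: MMParams) -> PartitionedVmax:
    """Isoform-specific Vmax as a parameter difference with SE by quadrature."""
    if not (total.converged and background.converged):
        raise DomainError("both input fits must have converged")
    return PartitionedVmax(
        Vmax=total.Vmax - background.Vmax,
        se=math.hypot(total.se_Vmax, background.se_Vmax),
    )


# ---------------------------------------------------------------------------
# inhibitor fractionation
# ---------------------------------------------------------------------------


def percent_inhibition(baseline: float, residual: float) -> float:
    """Percent of the baseline activity lost: 100·(baseline − residual)/baseline.

    Negative values (enhancement above baseline) are legal and flagged with a
    warning rather than clipped.
    """
    if baseline <= 0:
        raise DomainError(f"baseline activity must be > 0, got {baseline}")
    pct = 100.0 * (baseline - residual) / baseline
    if pct < 0:
        warnings.warn(
            f"residual {residual} exceeds baseline {baseline}: "
            f"enhancement of {-pct:.3g}%", stacklevel=2,
        )
    return pct


def normalize_to_baseline(activities: pd.DataFrame) -> pd.DataFrame:
    """Normalize an inhibition experiment to its 0-mM baseline.

    ``activities`` is the long table from the inhibition CSV schema
    (inhibitor, conc_mM, activity, replicate); rows at 0 mM are the common
    no-inhibitor control.  Returns one row per inhibitor × concentration with
    ``residual_pct`` (0 mM maps to exactly 100) and the complementary
    ``inhibited_pct``.
    """
    required = {"inhibitor", "conc_mM", "activity"}
    if not required.issubset(activities.columns):
        raise SchemaError(f"inhibition table must have columns {sorted(required)}")
    base_rows = activities[activities["conc_mM"] == 0]
    if len(base_rows) == 0:
        raise SchemaError("no 0-mM baseline group in the inhibition table")
    baseline = float(base_rows["activity"].mean())
    if baseline <= 0:
        raise DomainError(f"0-mM baseline mean must be > 0, got {baseline}")
    means = (
        activities.groupby(["inhibitor", "conc_mM"], sort=True)["activity"]
        .mean()
        .reset_index()
    )
    residual = np.where(
        means["conc_mM"] == 0, 100.0, 100.0 * means["activity"] / baseline
    )
    out = means.assign(residual_pct=residual, inhibited_pct=100.0 - residual)
    out.attrs["baseline_mean"] = baseline
    return out


def classify_isoform_dominance(
    table: pd.DataFrame, threshold: float = DOMINANCE_THRESHOLD
) -> Dominance:
    """Label the dominant isoform family from a normalized inhibition table.

    At the top shared concentration: IAP-dominant when L-Phe inhibition is at
    or above ``threshold`` while L-hArg inhibition is below it; TNAP-dominant
    for the mirror case; mixed otherwise (both high, as in large-intestinal
    segments, or both low).
    """
    for inh in INHIBITORS:
        if inh not in set(table["inhibitor"]):
            raise SchemaError(f"inhibition table is missing inhibitor {inh!r}")
    treated = table[table["conc_mM"] > 0]
    top = float(treated["conc_mM"].max())
    at_top = treated[treated["conc_mM"] == top]
    inhibited = {}
    for inh in INHIBITORS:
        rows = at_top[at_top["inhibitor"] == inh]
        if len(rows) == 0:
            raise SchemaError(
                f"inhibitor {inh!r} has no row at the top concentration {top} mM"
            )
        inhibited[inh] = float(rows["inhibited_pct"].iloc[0])
    phe, harg = inhibited["L-Phe"], inhibited["L-hArg"]
    if phe >= threshold and harg < threshold:
        return Dominance.IAP
    if harg >= threshold and phe < threshold:
        return Dominance.TNAP
    return Dominance.MIXED
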