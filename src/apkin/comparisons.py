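"""Comparison conventions and inference on kinetic parameter estimates.

Fold differences use the excess-over-baseline convention
``(max − min)/min`` — the convention under which, e.g., Km values of 280.35
and 37.70 µM differ by "6.4-fold" — with the direction (higher/lower)
reported separately.  A plain-ratio convention is exposed but never default.

Parameter estimates carry standard errors rather than raw replicates, so
pairs are compared by the pooled two-tailed t statistic
``t = (a − b)/√(se_a² + se_b²)`` with the conservative df = min(df_a, df_b).
Replicate-level endpoint comparisons use one-way ANOVA with Tukey HSD and a
compact letter display mirroring the superscript convention of kinetics
tables.  Significance is declared at p < 0.05 and a trend at p < 0.10.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .core_io import DomainError, SchemaError

ALPHA_SIGNIFICANT = 0.05
ALPHA_TREND = 0.10


@dataclass(frozen=True)
class EstimateWithSE:
    """A fitted parameter estimate with its SE and testing df."""

    value: float
    se: float
    df: int

    def __post_init__(self):
        if self.se < 0:
            raise DomainError("se must be >= 0")
        if self.df < 1:
            raise DomainError("df must be >= 1")


@dataclass(frozen=True)
class TTestResult:
    t: float
    p: float
    df: int
    significant: bool   # p < 0.05
    trend: bool         # p < 0.10
    degenerate: bool = False


@dataclass(frozen=True)
class AnovaTukeyResult:
    f_statistic: float
    p: float
    df_between: int
    df_within: int
    tukey: dict            # (label_a, label_b) -> adjusted p
    letters: dict          # label -> compact letter display string


# ---------------------------------------------------------------------------
# fold / percent arithmetic
# ---------------------------------------------------------------------------


def fold_difference(a: float, b: float, convention: str = "excess") -> float:
    """Fold difference between two positive quantities.

    ``excess`` (default): (max − min)/min, symmetric in its arguments.
    ``ratio``: max/min (exposed for cross-checks, never the reporting default).
    """
    if a <= 0 or b <= 0:
        raise DomainError("fold_difference requires positive inputs")
    hi, lo = max(a, b), min(a, b)
    if convention == "excess":
        return (hi - lo) / lo
    if convention == "ratio":
        return hi / lo
    raise SchemaError(f"unknown fold convention {convention!r}")


def fold_direction(reference: float, other: float) -> str:
    """'higher', 'lower' or 'equal': the direction of ``other`` vs reference."""
    if other > reference:
        return "higher"
    if other < reference:
        return "lower"
    return "equal"


def percent_change(reference: float, new: float, mode: str) -> float:
    """Percent change of ``new`` relative to ``reference``.

    ``increase``: 100·(new/reference − 1); ``reduction``:
    100·(reference − new)/reference.
    """
    if reference <= 0:
        raise DomainError("reference must be > 0")
    if mode == "increase":
        return 100.0 * (new / reference - 1.0)
    if mode == "reduction":
        return 100.0 * (reference - new) / reference
    raise SchemaError(f"unknown mode {mode!r}; expected 'increase' or 'reduction'")


def round_reported_percent(pct: float) -> int:
    """Round half away from zero to an integer, the prose reporting style."""
    return int(math.floor(abs(pct) + 0.5) * (1 if pct >= 0 else -1))


# ---------------------------------------------------------------------------
# inference
# ---------------------------------------------------------------------------


def pooled_estimate_ttest(a: EstimateWithSE, b: EstimateWithSE) -> TTestResult:
    """Pooled two-tailed t-test on two parameter estimates.

    Degenerate cases (both SEs zero) return p = 1 for equal values and p = 0
    otherwise, flagged.
    """
    se = math.hypot(a.se, b.se)
    df = min(a.df, b.df)
    if se == 0.0:
        equal = a.value == b.value
        p = 1.0 if equal else 0.0
        return TTestResult(t=0.0 if equal else math.inf, p=p, df=df,
                           significant=p < ALPHA_SIGNIFICANT,
                           trend=p < ALPHA_TREND, degenerate=True)
    t = (a.value - b.value) / se
    p = float(2.0 * stats.t.sf(abs(t), df))
    return TTestResult(t=t, p=p, df=df,
                       significant=p < ALPHA_SIGNIFICANT, trend=p < ALPHA_TREND)


def df_for_fit(n: int, n_params: int) -> int:
    """Default testing df for a fitted parameter: n − number of parameters."""
    df = n - n_params
    if df < 1:
        raise DomainError(f"non-positive df from n={n}, n_params={n_params}")
    return df


def _compact_letter_display(labels, sep_pairs: set) -> dict:
    """Greedy insert-and-absorb compact letter display.

    ``sep_pairs`` holds unordered pairs declared significantly different;
    groups sharing a letter are not significantly different.
    """
    letters: list[set] = []  # each entry: set of labels sharing that letter
    for lab in labels:
        placed = False
        for grp in letters:
            if all(frozenset((lab, other)) not in sep_pairs for other in grp):
                grp.add(lab)
                placed = True
        if not placed:
            letters.append({lab})
    # drop letter-groups fully contained in another (absorption)
    kept = [g for i, g in enumerate(letters)
            if not any(i != j and g < letters[j] for j in range(len(letters)))]
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    out = {lab: "" for lab in labels}
    for ch, grp in zip(alphabet, kept):
        for lab in grp:
            out[lab] += ch
    return out


def oneway_anova_tukey(groups: dict) -> AnovaTukeyResult:
    """One-way ANOVA with Tukey HSD multiple comparisons.

    ``groups`` maps a label to its replicate values (>= 2 each).  Returns the
    F statistic and p, pairwise Tukey-adjusted p values and a compact letter
    display (shared letter = not significantly different at 0.05).
    """
    if len(groups) < 2:
        raise SchemaError("need >= 2 groups")
    labels = list(groups)
    arrays = []
    for lab in labels:
        vals = np.asarray(groups[lab], dtype=float)
        if len(vals) < 2:
            raise SchemaError(f"group {lab!r} has < 2 replicates")
        arrays.append(vals)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # constant inputs trigger scipy warnings
        f_stat, p = stats.f_oneway(*arrays)
    f_stat = float(np.nan_to_num(f_stat, nan=0.0))
    p = float(p) if np.isfinite(p) else 1.0

    k = len(arrays)
    n_total = sum(len(a) for a in arrays)
    df_within = n_total - k
    means = [float(np.mean(a)) for a in arrays]
    sse = sum(float(np.sum((a - m) ** 2)) for a, m in zip(arrays, means))
    mse = sse / df_within if df_within > 0 else 0.0

    tukey: dict = {}
    sep: set = set()
    for (i, la), (j, lb) in itertools.combinations(enumerate(labels), 2):
        ni, nj = len(arrays[i]), len(arrays[j])
        se = math.sqrt(mse / 2.0 * (1.0 / ni + 1.0 / nj))
        if se == 0.0:
            q = 0.0 if means[i] == means[j] else math.inf
        else:
            q = abs(means[i] - means[j]) / se
        adj_p = float(stats.studentized_range.sf(q, k, df_within)) if math.isfinite(q) else 0.0
        tukey[(la, lb)] = adj_p
        if adj_p < ALPHA_SIGNIFICANT:
            sep.add(frozenset((la, lb)))
    letters = _compact_letter_display(labels, sep)
    return AnovaTukeyResult(
        f_statistic=f_stat, p=p, df_between=k - 1, df_within=df_within,
        tukey=tukey, letters=letters,
    )
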