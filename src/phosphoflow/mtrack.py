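"""M-Track proximity-assay densitometry statistics.

Each Western blot carries a 4-point dilution series of a control sample; a
polynomial (degree 2 for antibody series 1, degree 1 for series 2) is fitted
per channel to log2 signal vs log2 loading.  Test-lane signals are inverted
through their blot's fitted curve onto the common "equivalent loading" scale,
which corrects for unequal loading within a blot and normalizes between
blots.  The proximity signal of a lane is the difference of the equivalent
loadings of the methylation (me3K9H3) and expression (HA) channels; signals
are rescaled by subtracting the mean proximity of the negative control
(prey-tag only, no bait).  Candidates are called by a one-tailed (greater)
Welch t-test of each bait's replicate proximities against the pooled
negative-control proximities, with Benjamini-Hochberg q-values over the bait
family and significance tiers at q < 0.05 and q < 0.01.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import ConfigError, FormatError
from .simulate import DILUTION_LABEL, NEGATIVE_CONTROL

logger = logging.getLogger(__name__)

VAR_FLOOR = 1e-8  # variance floor so degenerate zero-variance groups test


@dataclass
class DilutionCurve:
    """Least-squares polynomial of log2 signal vs log2 loading, fitted on
    one blot's 4-point dilution series for one channel."""

    blot_id: str
    channel: str
    degree: int
    coefficients: np.ndarray  # highest degree first
    residual_norm: float
    loading_range: tuple[float, float]  # log2 loadings covered by the series

    def __call__(self, log2_loading: float) -> float:
        return float(np.polyval(self.coefficients, log2_loading))

    def invert(self, log2_signal: float) -> float:
        """Equivalent log2 loading producing the observed log2 signal."""
        if self.degree == 1:
            a, b = self.coefficients
            if a == 0:
                raise ConfigError("flat dilution curve cannot be inverted")
            return float((log2_signal - b) / a)
        a2, a1, a0 = self.coefficients
        disc = a1 * a1 - 4 * a2 * (a0 - log2_signal)
        if disc < 0:
            # signal outside the parabola's range: nearest vertex
            return float(-a1 / (2 * a2))
        r = math.sqrt(disc)
        roots = ((-a1 + r) / (2 * a2), (-a1 - r) / (2 * a2))
        lo, hi = self.loading_range
        mid = (lo + hi) / 2
        # monotone over the dilution range, so at most one root is near it
        return float(min(roots, key=lambda x: abs(x - mid)))


@dataclass
class ProximityResult:
    """Per-bait proximity statistic with multiplicity-corrected q-value."""

    bait: str
    proximity_per_replicate: np.ndarray
    mean_proximity: float
    p_value: float
    q_value: float
    significance_tier: str  # 'q<0.01', 'q<0.05' or 'ns'


def fit_dilution_curve(series_points, degree: int) -> DilutionCurve:
    """Fit the stated-degree polynomial to exactly 4 (loading, log2 signal)
    points with distinct loadings; loadings are on the linear scale.

    A degree-2 fit that is not monotone over the dilution range falls back
    to degree 1 with a warning (the curve must be invertible).
    """
    pts = list(series_points)
    if degree not in (1, 2):
        raise ConfigError("degree must be 1 or 2")
    if len(pts) != 4:
        raise ConfigError(f"dilution series must have exactly 4 points, got {len(pts)}")
    loadings = np.array([p[0] for p in pts], dtype=float)
    signals = np.array([p[1] for p in pts], dtype=float)
    if len(np.unique(loadings)) != 4:
        raise ConfigError("dilution loadings must be distinct")
    x = np.log2(loadings)
    coef = np.polyfit(x, signals, degree)
    if degree == 2 and coef[0] != 0:
        # invertibility: the parabola's vertex must not fall strictly inside
        # the dilution range (tolerance absorbs exact-fit rounding)
        vertex = -coef[1] / (2 * coef[0])
        tol = 1e-9 * (x.max() - x.min())
        if x.min() + tol < vertex < x.max() - tol:
            logger.warning(
                "degree-2 dilution curve not monotone over the series; "
                "falling back to degree 1"
            )
            coef = np.polyfit(x, signals, 1)
            degree = 1
    residual = float(np.linalg.norm(signals - np.polyval(coef, x)))
    return DilutionCurve(
        blot_id="", channel="", degree=degree, coefficients=coef,
        residual_norm=residual, loading_range=(float(x.min()), float(x.max())),
    )


def fit_blot_curves(
    table: pd.DataFrame, dilution_label: str = DILUTION_LABEL
) -> dict[tuple[str, str], DilutionCurve]:
    """Fit per-(blot, channel) dilution curves from the table's dilution
    rows; degree 2 for series 1, degree 1 for series 2."""
    curves: dict[tuple[str, str], DilutionCurve] = {}
    dil = table[table["bait"] == dilution_label]
    if dil.empty:
        raise FormatError("densitometry table has no dilution-series rows")
    for (blot, channel), grp in dil.groupby(["blot_id", "channel"]):
        series = int(grp["series"].iloc[0])
        degree = 2 if series == 1 else 1
        pts = list(zip(grp["loading"], np.log2(grp["area"])))
        curve = fit_dilution_curve(pts, degree)
        curve.blot_id, curve.channel = str(blot), str(channel)
        curves[(str(blot), str(channel))] = curve
    return curves


def correct_and_score(
    table: pd.DataFrame,
    curves: dict[tuple[str, str], DilutionCurve] | None = None,
    dilution_label: str = DILUTION_LABEL,
) -> pd.DataFrame:
    """Loading-correct each lane and compute its proximity signal.

    Returns one row per (blot, bait, replicate) with columns bait, replicate,
    series and proximity = equivalent-loading(me3) - equivalent-loading(HA).
    """
    if curves is None:
        curves = fit_blot_curves(table, dilution_label)
    lanes = table[table["bait"] != dilution_label]
    rows = []
    for (blot, bait, rep), grp in lanes.groupby(
        ["blot_id", "bait", "replicate"], sort=True
    ):
        areas = dict(zip(grp["channel"], grp["area"]))
        if "me3" not in areas or "ha" not in areas:
            raise FormatError(f"lane ({blot}, {bait}, {rep}) lacks a channel")
        prox = 0.0
        for channel, sign in (("me3", 1.0), ("ha", -1.0)):
            curve = curves.get((str(blot), channel))
            if curve is None:
                raise FormatError(f"no dilution curve for ({blot}, {channel})")
            prox += sign * curve.invert(math.log2(areas[channel]))
        rows.append(
            (str(blot), str(bait), str(rep), int(grp["series"].iloc[0]), prox)
        )
    return pd.DataFrame(
        rows, columns=["blot_id", "bait", "replicate", "series", "proximity"]
    )


def rescale_to_control(
    proximities: pd.DataFrame, negative_control_label: str = NEGATIVE_CONTROL
) -> pd.DataFrame:
    """Subtract the mean negative-control proximity, so the control mean is
    exactly 0; errors when no control lane is present."""
    mask = proximities["bait"] == negative_control_label
    if not mask.any():
        raise FormatError(
            f"no negative-control records ({negative_control_label!r})"
        )
    shift = float(proximities.loc[mask, "proximity"].mean())
    out = proximities.copy()
    out["proximity"] = out["proximity"] - shift
    return out


def _welch_one_tailed_greater(x: np.ndarray, y: np.ndarray) -> float:
    """Welch's t-test p-value for mean(x) > mean(y), with a variance floor
    for degenerate zero-variance groups."""
    nx, ny = len(x), len(y)
    vx = max(float(np.var(x, ddof=1)), VAR_FLOOR)
    vy = max(float(np.var(y, ddof=1)), VAR_FLOOR)
    se2 = vx / nx + vy / ny
    t = (float(np.mean(x)) - float(np.mean(y))) / math.sqrt(se2)
    df = se2 ** 2 / ((vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1))
    return float(stats.t.sf(t, df))


def test_baits(
    rescaled: pd.DataFrame,
    negative_control_label: str = NEGATIVE_CONTROL,
    n_min: int = 3,
) -> list[ProximityResult]:
    """One-tailed Welch test of every bait against the pooled negative
    control, BH-corrected over the tested bait family.

    Baits with fewer than 2 replicates are skipped with a warning; baits
    with fewer than ``n_min`` are tested but flagged in the log.
    """
    control = rescaled.loc[
        rescaled["bait"] == negative_control_label, "proximity"
    ].to_numpy()
    if len(control) < 2:
        raise FormatError("negative control needs >= 2 replicates")
    tested: list[tuple[str, np.ndarray, float]] = []
    for bait, grp in rescaled[rescaled["bait"] != negative_control_label].groupby(
        "bait", sort=True
    ):
        values = grp["proximity"].to_numpy()
        if len(values) < 2:
            logger.warning("bait %r skipped: only %d replicate(s)", bait, len(values))
            continue
        if len(values) < n_min:
            logger.info("bait %r tested with n=%d < n_min=%d", bait, len(values), n_min)
        tested.append((str(bait), values, _welch_one_tailed_greater(values, control)))
    if not tested:
        return []
    pvals = np.array([t[2] for t in tested])
    _, qvals, _, _ = multipletests(pvals, method="fdr_bh")
    results = []
    for (bait, values, p), q in zip(tested, qvals):
        tier = "q<0.01" if q < 0.01 else ("q<0.05" if q < 0.05 else "ns")
        results.append(
            ProximityResult(
                bait=bait,
                proximity_per_replicate=values,
                mean_proximity=float(np.mean(values)),
                p_value=float(p),
                q_value=float(q),
                significance_tier=tier,
            )
        )
    return results


def results_to_frame(results: list[ProximityResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "bait": r.bait,
                "n": len(r.proximity_per_replicate),
                "mean_proximity": r.mean_proximity,
                "p_value": r.p_value,
                "q_value": r.q_value,
                "tier": r.significance_tier,
            }
            for r in results
        ],
        columns=["bait", "n", "mean_proximity", "p_value", "q_value", "tier"],
    )
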