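"""Region-wise correlation of qMRI maps with modelled composition,
best-fit curve families, and nonparametric group comparisons.

The central statistic is Spearman's rank correlation between a fitted
relaxation map (T1, T1rho, T2*) and a modelled tissue parameter (fluid,
collagen, proteoglycan fraction or mean fiber angle), computed pixel-wise
within each lateral region. Rank correlation is used because the
composition–relaxation relationships are expected to be monotone but not
linear.

Relationships are additionally summarized by parametric curve fits —
``a exp(b * phi) + c`` for volume fractions and ``a sin(b * theta) + c``
for the fiber angle — and group differences are tested nonparametrically
(Mann–Whitney U across the two regions, Kruskal–Wallis across the three
depth zones with Dunn's post-hoc pairwise z-tests when the omnibus test
is significant).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.optimize import least_squares
from statsmodels.stats.multitest import multipletests

from .geometry import REGIONS, ZONES, RegionLabels, ZoneLabels

__all__ = [
    "CurveFit",
    "GroupComparison",
    "spearman",
    "correlation_table",
    "fit_exponential",
    "fit_sinusoidal",
    "compare_groups",
    "zonal_summary",
    "significance_stars",
]

#: model-parameter columns of the correlation table, in display order
MODEL_PARAMS = ("FF", "CO", "PG", "CFO")
QMRI_PARAMS = ("T1", "T1RHO", "T2STAR")

#: above this sample size the t-approximation replaces exact permutation
EXACT_PERM_MAX_N = 8


def significance_stars(p: float) -> str:
    """Three-tier significance annotation: * / ** / *** at 0.05/0.01/0.001."""
    if not np.isfinite(p):
        return "ns"
    if p <= 0.001:
        return "***"
    if p <= 0.01:
        return "**"
    if p <= 0.05:
        return "*"
    return "ns"


def _exact_perm_p(x: np.ndarray, y: np.ndarray, rho_obs: float) -> float:
    """Two-sided exact permutation p-value for Spearman's rho (small n)."""
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    n = len(rx)
    rx = (rx - rx.mean()) / np.sqrt(np.sum((rx - rx.mean()) ** 2))
    ry_c = ry - ry.mean()
    denom = np.sqrt(np.sum(ry_c**2))
    count = 0
    total = 0
    for perm in itertools.permutations(range(n)):
        rho = float(rx[list(perm)] @ ry_c) / denom
        if abs(rho) >= abs(rho_obs) - 1e-12:
            count += 1
        total += 1
    return count / total


def spearman(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Tie-corrected Spearman rank correlation with two-sided p-value.

    Equivalent to the Pearson correlation of midranks. For very small
    samples (n <= 8) the p-value is an exact permutation probability;
    otherwise the usual t-approximation is used. Returns ``(nan, nan)``
    when either variable has zero rank variance.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length vectors")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("inputs must be finite")
    if np.ptp(sps.rankdata(x)) == 0 or np.ptp(sps.rankdata(y)) == 0:
        return float("nan"), float("nan")
    rho, p = sps.spearmanr(x, y)
    if x.size <= EXACT_PERM_MAX_N:
        p = _exact_perm_p(x, y, rho)
    return float(rho), float(p)


def correlation_table(
    qmaps: dict[str, np.ndarray],
    mmaps,
    regions: RegionLabels,
    qc_masks: dict[str, np.ndarray] | None = None,
) -> pd.DataFrame:
    """Pixel-wise Spearman correlations for every (qMRI, model) pair and region.

    ``qmaps`` maps sequence names to fitted relaxation maps; ``mmaps`` is
    a :class:`~cartiqmap.tissue_model.ModelledMaps`; ``qc_masks``
    optionally restricts each qMRI map to QC-passing pixels. Produces one
    row per (qMRI, model, region) combination — 24 for the full design —
    with rho, two-sided p, pixel count and significance stars.
    """
    mdict = mmaps.as_dict() if hasattr(mmaps, "as_dict") else dict(mmaps)
    rows = []
    for qname, qmap in qmaps.items():
        valid_q = np.isfinite(qmap)
        if qc_masks and qname in qc_masks:
            valid_q &= qc_masks[qname].astype(bool)
        for mname in MODEL_PARAMS:
            mmap = mdict[mname]
            for region in REGIONS:
                sel = regions.region_mask(region) & valid_q & np.isfinite(mmap)
                n = int(sel.sum())
                if n < 3:
                    raise ValueError(f"region {region} has {n} usable pixels (< 3)")
                rho, p = spearman(qmap[sel], mmap[sel])
                rows.append(
                    {
                        "qmri": qname,
                        "model": mname,
                        "region": region,
                        "rho_s": rho,
                        "p_value": p,
                        "n_pixels": n,
                        "stars": significance_stars(p),
                    }
                )
    return pd.DataFrame(rows)


@dataclass
class CurveFit:
    """Parametric best-fit summary for one (predictor, response) pairing."""

    family: str
    a: float
    b: float
    c: float
    r2: float
    n: int
    converged: bool


def _r2(resid: np.ndarray, y: np.ndarray) -> float:
    sst = float(np.sum((y - y.mean()) ** 2))
    if sst == 0:
        return float("nan")
    return 1.0 - float(np.sum(resid**2)) / sst


def _curve_lsq(model, x, y, starts) -> tuple[np.ndarray, np.ndarray] | None:
    best = None
    for p0 in starts:
        try:
            res = least_squares(lambda p: model(x, p) - y, p0, xtol=1e-12, ftol=1e-12)
        except Exception:
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        return None
    return best.x, best.fun


def fit_exponential(phi: np.ndarray, q: np.ndarray) -> CurveFit:
    """Least-squares fit of ``a exp(b phi) + c`` with multi-start over b.

    Degenerate responses (zero variance) are flagged unconverged rather
    than raised; the reported R² always refers to the realized residuals.
    """
    phi = np.asarray(phi, dtype=float)
    q = np.asarray(q, dtype=float)
    if phi.size < 4:
        raise ValueError("need at least 4 points")
    span = float(q.max() - q.min())
    if span == 0:
        return CurveFit("exponential", 0.0, 0.0, float(q[0]), float("nan"), q.size, False)

    def model(x, p):
        return p[0] * np.exp(np.clip(p[1] * x, -50, 50)) + p[2]

    scale = max(float(np.ptp(phi)), 1e-6)
    starts = [
        [span, 1.0 / scale, float(q.min())],
        [-span, 1.0 / scale, float(q.max())],
        [span, -1.0 / scale, float(q.min())],
        [-span, -1.0 / scale, float(q.max())],
        [span, 2.0, float(q.mean())],
    ]
    sol = _curve_lsq(model, phi, q, starts)
    if sol is None:
        return CurveFit("exponential", *[float("nan")] * 4, q.size, False)
    p, resid = sol
    r2 = _r2(resid, q)
    return CurveFit("exponential", float(p[0]), float(p[1]), float(p[2]), r2, q.size, True)


def fit_sinusoidal(theta_deg: np.ndarray, q: np.ndarray) -> CurveFit:
    """Least-squares fit of ``a sin(b theta) + c`` (theta in radians internally).

    The reported ``b`` is in radian^-1 of the angle expressed in radians;
    a value of 1 corresponds to one quarter period over a 90° angular
    range.
    """
    theta = np.deg2rad(np.asarray(theta_deg, dtype=float))
    q = np.asarray(q, dtype=float)
    if theta.size < 4:
        raise ValueError("need at least 4 points")
    span = float(q.max() - q.min())
    if span == 0:
        return CurveFit("sinusoidal", 0.0, 0.0, float(q[0]), float("nan"), q.size, False)

    def model(x, p):
        return p[0] * np.sin(p[1] * x) + p[2]

    starts = [
        [span / 2.0, b0, float(q.mean())]
        for b0 in (0.5, 1.0, 2.0, -1.0)
    ]
    sol = _curve_lsq(model, theta, q, starts)
    if sol is None:
        return CurveFit("sinusoidal", *[float("nan")] * 4, q.size, False)
    p, resid = sol
    if p[0] < 0:  # (a, b) -> (-a, -b) leaves the model invariant
        p = np.array([-p[0], -p[1], p[2]])
    r2 = _r2(resid, q)
    degenerate = abs(p[0]) < 1e-9 * max(1.0, abs(float(q.mean())))
    return CurveFit(
        "sinusoidal", float(p[0]), float(p[1]), float(p[2]), r2, q.size, not degenerate
    )


@dataclass
class GroupComparison:
    """Omnibus nonparametric comparison with optional post-hoc table."""

    design: str
    test: str
    statistic: float
    p_value: float
    posthoc: pd.DataFrame | None = None


def _dunn_posthoc(
    groups: dict[str, np.ndarray], adjust: str = "bonferroni"
) -> pd.DataFrame:
    """Dunn's pairwise z-tests on mean ranks with tie correction.

    For groups i, j with mean ranks Ri, Rj over the pooled ranking of N
    observations, z = (Ri - Rj) / sqrt([N(N+1)/12 - T/(12(N-1))] (1/ni + 1/nj))
    where T = sum(t^3 - t) over tie groups. Two-sided normal p-values,
    adjusted across the pairwise family (none | bonferroni | holm).
    """
    names = list(groups)
    pooled = np.concatenate([groups[g] for g in names])
    n_total = pooled.size
    ranks = sps.rankdata(pooled)
    mean_ranks, sizes = {}, {}
    start = 0
    for g in names:
        k = groups[g].size
        mean_ranks[g] = float(ranks[start : start + k].mean())
        sizes[g] = k
        start += k
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (12.0 * (n_total - 1))
    var_unit = n_total * (n_total + 1) / 12.0 - tie_term

    rows = []
    for g1, g2 in itertools.combinations(names, 2):
        se = np.sqrt(var_unit * (1.0 / sizes[g1] + 1.0 / sizes[g2]))
        z = (mean_ranks[g1] - mean_ranks[g2]) / se
        p = 2.0 * sps.norm.sf(abs(z))
        rows.append({"group_1": g1, "group_2": g2, "z": z, "p_raw": min(p, 1.0)})
    table = pd.DataFrame(rows)
    if adjust == "none":
        table["p_adj"] = table["p_raw"]
    else:
        table["p_adj"] = multipletests(table["p_raw"], method=adjust)[1]
    table["significant"] = table["p_adj"] < 0.05
    return table


def compare_groups(
    values: np.ndarray,
    labels: np.ndarray,
    design: str,
    adjust: str = "bonferroni",
) -> GroupComparison:
    """Nonparametric comparison across regions (two groups) or zones (three).

    ``design="regions"`` runs a two-sided Mann–Whitney U test;
    ``design="zones"`` runs Kruskal–Wallis followed, when the omnibus p is
    below 0.05, by Dunn's post-hoc pairwise comparisons with the requested
    multiplicity adjustment.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    names = REGIONS if design == "regions" else ZONES
    if design not in ("regions", "zones"):
        raise ValueError("design must be 'regions' or 'zones'")
    groups = {}
    for i, name in enumerate(names):
        sel = (labels == i) & np.isfinite(values)
        if sel.sum() < 2:
            raise ValueError(f"group {name} has fewer than 2 observations")
        groups[name] = values[sel]

    if design == "regions":
        stat, p = sps.mannwhitneyu(groups["CR"], groups["PR"], alternative="two-sided")
        return GroupComparison(design, "mann-whitney-u", float(stat), float(p))

    stat, p = sps.kruskal(*groups.values())
    posthoc = _dunn_posthoc(groups, adjust=adjust) if p < 0.05 else None
    return GroupComparison(design, "kruskal-wallis", float(stat), float(p), posthoc)


def zonal_summary(
    map2d: np.ndarray,
    zones: ZoneLabels,
    regions: RegionLabels,
    value_name: str = "value",
) -> pd.DataFrame:
    """Mean ± SD and pixel count per (zone, region) cell.

    Cells with no finite pixels are reported with NaN mean/SD and zero
    count rather than dropped, so the table shape is always 3 zones x 2
    regions.
    """
    map2d = np.asarray(map2d, dtype=float)
    rows = []
    for zi, zone in enumerate(ZONES):
        for ri, region in enumerate(REGIONS):
            sel = (zones.labels == zi) & (regions.labels == ri) & np.isfinite(map2d)
            vals = map2d[sel]
            rows.append(
                {
                    "zone": zone,
                    "region": region,
                    "parameter": value_name,
                    "mean": float(vals.mean()) if vals.size else float("nan"),
                    "sd": float(vals.std(ddof=1)) if vals.size > 1 else (0.0 if vals.size == 1 else float("nan")),
                    "n_pixels": int(vals.size),
                }
            )
    return pd.DataFrame(rows)
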