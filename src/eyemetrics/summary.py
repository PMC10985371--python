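"""Eye- and cohort-level statistics: medians, IQRs, optimal-Barlow fractions,
allometric correlations, and per-ommatidium eye maps.

Quantile convention: linear interpolation (numpy default), quartiles at
p = 0.25 / 0.75, IQR = Q3 − Q1; the median of an odd-length sample is exactly
its middle element.  Excluded metric records never enter a summary; a count
of exclusions per reason is always carried alongside.

The "optimal" Barlow interval is the closed range [0.4, 1.0] — the band in
which an eye neither oversamples (wasting facets on detail diffraction has
already destroyed) nor undersamples the scene.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats as _st

from .geometry import OpticalConstants, DEFAULT_CONSTANTS

__all__ = [
    "EyeSummary",
    "CorrelationResult",
    "summarize_eye",
    "aggregate_individuals",
    "pearson_correlation",
    "p_value_from_r",
    "render_eye_maps",
]


@dataclass
class EyeSummary:
    """Distribution statistics of one individual's eye."""

    individual_id: str
    n_ommatidia: int
    median_D_um: float
    iqr_D_um: float
    median_theta_deg: float
    iqr_theta_deg: float
    median_dphi_deg: float
    iqr_dphi_deg: float
    median_barlow: float
    iqr_barlow: float
    frac_barlow_optimal: float
    typical_cone_length_um: float | None = None
    cone_ratio: float | None = None
    wingspan_mm: float | None = None
    exclusion_counts: dict = field(default_factory=dict)

    def to_row(self) -> dict:
        row = asdict(self)
        row.pop("exclusion_counts")
        return row


@dataclass
class CorrelationResult:
    r: float
    p_value: float
    n: int
    df: int


def _median_iqr(values: np.ndarray) -> tuple[float, float]:
    q1, med, q3 = np.percentile(values, [25, 50, 75])
    return float(med), float(q3 - q1)


def summarize_eye(
    metrics: pd.DataFrame,
    *,
    individual_id: str = "",
    typical_cone_length_um: float | None = None,
    cone_ratio: float | None = None,
    wingspan_mm: float | None = None,
    constants: OpticalConstants = DEFAULT_CONSTANTS,
) -> EyeSummary:
    """Median/IQR of D, θ, Δφ and the Barlow ratio over included records.

    ``frac_barlow_optimal`` is the fraction of included ommatidia whose
    Barlow ratio falls in the closed optimal band.  Raises if every record
    was excluded.
    """
    if "excluded" in metrics:
        included = metrics.loc[~metrics["excluded"]]
        reasons = metrics.loc[metrics["excluded"], "reason"]
        exclusion_counts = reasons.value_counts().to_dict()
    else:
        included = metrics
        exclusion_counts = {}
    if len(included) == 0:
        raise ValueError("all metric records are excluded; nothing to summarize")

    med_D, iqr_D = _median_iqr(included["D_um"].to_numpy())
    med_th, iqr_th = _median_iqr(included["theta_deg"].to_numpy())
    med_dp, iqr_dp = _median_iqr(included["delta_phi_deg"].to_numpy())
    barlow = included["barlow_ratio"].to_numpy()
    med_b, iqr_b = _median_iqr(barlow)
    in_band = (barlow >= constants.optimal_barlow_low) & (
        barlow <= constants.optimal_barlow_high
    )
    return EyeSummary(
        individual_id=individual_id,
        n_ommatidia=int(len(included)),
        median_D_um=med_D,
        iqr_D_um=iqr_D,
        median_theta_deg=med_th,
        iqr_theta_deg=iqr_th,
        median_dphi_deg=med_dp,
        iqr_dphi_deg=iqr_dp,
        median_barlow=med_b,
        iqr_barlow=iqr_b,
        frac_barlow_optimal=float(in_band.mean()),
        typical_cone_length_um=typical_cone_length_um,
        cone_ratio=cone_ratio,
        wingspan_mm=wingspan_mm,
        exclusion_counts=exclusion_counts,
    )


def aggregate_individuals(
    summaries: list[EyeSummary],
) -> tuple[pd.DataFrame, dict]:
    """Cohort table plus cross-individual averages.

    The averages follow the "average median across individuals" convention:
    for each metric, the mean of the per-individual medians, the min/max of
    those medians, and the mean of the per-individual IQRs.
    """
    if len(summaries) == 0:
        raise ValueError("need at least one eye summary")
    cohort = pd.DataFrame([s.to_row() for s in summaries])
    averages: dict = {"n_individuals": len(summaries)}
    for metric in ("D_um", "theta_deg", "dphi_deg", "barlow"):
        med = cohort[f"median_{metric}"]
        averages[f"mean_median_{metric}"] = float(med.mean())
        averages[f"min_median_{metric}"] = float(med.min())
        averages[f"max_median_{metric}"] = float(med.max())
        averages[f"mean_iqr_{metric}"] = float(cohort[f"iqr_{metric}"].mean())
    averages["mean_frac_barlow_optimal"] = float(cohort["frac_barlow_optimal"].mean())
    return cohort, averages


def p_value_from_r(r: float, n: int) -> float:
    """Two-sided p for a sample Pearson r via t = r·sqrt((n−2)/(1−r²)), df = n−2."""
    if n < 3:
        raise ValueError("need n >= 3")
    if not -1.0 <= r <= 1.0:
        raise ValueError("r must lie in [-1, 1]")
    if abs(r) == 1.0:
        return 0.0
    df = n - 2
    t = abs(r) * np.sqrt(df / (1.0 - r * r))
    return float(2.0 * _st.t.sf(t, df))


def pearson_correlation(x, y) -> CorrelationResult:
    """Sample Pearson correlation with a t-transform two-sided p-value."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1D arrays of equal length")
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 observations")
    xc = x - x.mean()
    yc = y - y.mean()
    sx = np.sqrt((xc * xc).sum())
    sy = np.sqrt((yc * yc).sum())
    if sx == 0 or sy == 0:
        raise ValueError("zero variance in x or y")
    r = float(np.clip((xc * yc).sum() / (sx * sy), -1.0, 1.0))
    return CorrelationResult(r=r, p_value=p_value_from_r(r, n), n=n, df=n - 2)


_MAP_METRICS = {
    "D_um": "Ommatidial diameter D (μm)",
    "theta_deg": "Resolving power θ (°)",
    "delta_phi_deg": "Interommatidial angle Δφ (°)",
    "barlow_ratio": "Barlow ratio Δφ/θ",
}


def render_eye_maps(
    metrics: pd.DataFrame,
    out_dir,
    *,
    fmt: str = "png",
    dpi: int = 120,
) -> list:
    """Per-ommatidium eye maps: one 3D scatter per metric, colored by value.

    Only included records are drawn; each point is one ommatidium at its cone
    center.  Output is deterministic for fixed input (fixed canvas, no
    timestamps in metadata).
    """
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt
    from pathlib import Path

    included = metrics.loc[~metrics["excluded"]] if "excluded" in metrics else metrics
    if len(included) == 0:
        raise ValueError("no included ommatidia to plot")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for col, title in _MAP_METRICS.items():
        fig = plt.figure(figsize=(6, 5))
        ax = fig.add_subplot(111, projection="3d")
        sc = ax.scatter(
            included["x_um"],
            included["y_um"],
            included["z_um"],
            c=included[col],
            s=8,
            cmap="viridis",
        )
        fig.colorbar(sc, ax=ax, shrink=0.7, label=title)
        ax.set_xlabel("x (μm)")
        ax.set_ylabel("y (μm)")
        ax.set_zlabel("z (μm)")
        ax.set_title(title)
        path = out_dir / f"eye_map_{col}.{fmt}"
        metadata = {"Date": None} if fmt == "svg" else {"Software": "eyemetrics"}
        fig.savefig(path, dpi=dpi, metadata=metadata)
        plt.close(fig)
        paths.append(path)
    return paths
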