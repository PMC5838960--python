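"""In-silico mixing model and MA-plot ratio records.

The signal of miRNA *i* in a mixture is modeled as an additive, linear
combination of the pure-component signals weighted by the design
fractions: ``S_i,mix = sum_c S_i,c * phi_c,mix``.  Predicted log2 ratios
come from pushing linear-scale pure means through this model and logging;
observed log2 ratios are differences of means of the log2 replicate
values for each mixture.  Both are presented in Bland-Altman (MA)
coordinates: M = log2 ratio between the mixtures, A = average log2
signal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .design import MixtureDesign, SampleManifest
from .ingest import Log2Table
from .selectivity import PureProfile

__all__ = [
    "PredictedMixtures",
    "RatioTable",
    "LoessBand",
    "predict_mixture_signals",
    "predicted_ratios",
    "observed_ratios",
    "loess_band",
]


@dataclass
class PredictedMixtures:
    """Predicted linear-scale mixture signals, miRNA x mixture."""

    signals: pd.DataFrame

    def __post_init__(self) -> None:
        if (self.signals.to_numpy() < 0).any():
            raise ValueError("predicted mixture signals must be nonnegative")


#: MA-coordinate records: a DataFrame indexed by miRNA id with columns
#: ``M`` (log2 ratio, first vs second mixture) and ``A`` (average log2
#: signal); ``.attrs["source"]`` is ``"predicted"`` or ``"observed"``.
RatioTable = pd.DataFrame


def predict_mixture_signals(
    profile: PureProfile, design: MixtureDesign
) -> PredictedMixtures:
    """Apply the linear mixing model: predicted = pure means @ phi.

    The profile must carry one column per design component (any order);
    columns are aligned by name before the dot product.
    """
    missing = [c for c in design.component_ids if c not in profile.components]
    if missing:
        raise ValueError(f"profile lacks design components: {missing}")
    extra = [c for c in profile.components if c not in design.component_ids]
    if extra:
        raise ValueError(f"profile has components unknown to the design: {extra}")
    means = profile.linear_means[list(design.component_ids)]
    pred = means.to_numpy() @ design.phi
    return PredictedMixtures(
        pd.DataFrame(pred, index=means.index, columns=list(design.mixture_ids))
    )


def predicted_ratios(pred: PredictedMixtures, pseudocount: float = 1.0) -> RatioTable:
    """MA coordinates of the modeled mixtures.

    M = log2(S_mix1 + pc) - log2(S_mix2 + pc); A is their mean.  The same
    pseudocount as the observed-data log2 transform keeps the two scales
    comparable.
    """
    if pred.signals.shape[1] != 2:
        raise ValueError("predicted ratios are defined for exactly 2 mixtures")
    s = pred.signals.to_numpy() + pseudocount
    if (s <= 0).any():
        raise ValueError("signal + pseudocount must be positive")
    logged = np.log2(s)
    out = pd.DataFrame(
        {"M": logged[:, 0] - logged[:, 1], "A": logged.mean(axis=1)},
        index=pred.signals.index,
    )
    out.attrs["source"] = "predicted"
    out.attrs["pseudocount"] = pseudocount
    return out


def observed_ratios(
    log2_table: Log2Table, manifest: Optional[SampleManifest] = None
) -> RatioTable:
    """MA coordinates of the measured mixtures.

    Per miRNA, M is the difference of the mean log2 replicate values of
    the two mixtures and A is the mean of those two means.
    """
    manifest = manifest or log2_table.manifest
    mixes = manifest.mixtures()
    if len(mixes) != 2:
        raise ValueError(f"observed ratios need exactly 2 mixtures, found {mixes}")
    means = []
    for m in mixes:
        cols = manifest.samples_for_role(f"mix:{m}")
        if not cols:
            raise ValueError(f"no samples for mixture {m!r} in manifest")
        means.append(log2_table.values[cols].mean(axis=1))
    out = pd.DataFrame(
        {"M": means[0] - means[1], "A": (means[0] + means[1]) / 2.0}
    )
    out.attrs["source"] = "observed"
    return out


@dataclass
class LoessBand:
    """A loess curve with a pointwise confidence band on an A-grid."""

    grid: np.ndarray
    fit: np.ndarray
    lower: Optional[np.ndarray]
    upper: Optional[np.ndarray]
    span: float
    confidence: float


def _local_poly_fit(
    x: np.ndarray, y: np.ndarray, x0: float, k: int, degree: int
) -> tuple[float, float]:
    """Tricube-weighted polynomial fit at x0 using the k nearest points.

    Returns the fitted value and ||l(x0)||, the norm of the equivalent
    smoother weights (so var = sigma^2 * ||l||^2).
    """
    d = np.abs(x - x0)
    idx = np.argsort(d, kind="stable")[:k]
    h = d[idx].max()
    if h == 0:
        h = 1.0
    w = (1 - np.minimum(d[idx] / h, 1.0) ** 3) ** 3
    w = np.maximum(w, 1e-12)
    xc = x[idx] - x0
    X = np.vander(xc, degree + 1, increasing=True)
    WX = X * w[:, None]
    XtWX = X.T @ WX
    XtWy = WX.T @ y[idx]
    try:
        beta = np.linalg.solve(XtWX, XtWy)
        # l(x0)^T = e1^T (X'WX)^-1 X'W
        l = np.linalg.solve(XtWX, WX.T)[0]
    except np.linalg.LinAlgError:
        beta, *_ = np.linalg.lstsq(XtWX, XtWy, rcond=None)
        l = np.linalg.pinv(XtWX)[0] @ WX.T
    return float(beta[0]), float(np.sqrt(np.sum(l**2)))


def loess_band(
    records: RatioTable,
    class_subset: Optional[Sequence[str]] = None,
    span: float = 0.75,
    degree: int = 2,
    n_grid: int = 50,
    confidence: float = 0.95,
    min_points: int = 10,
) -> Optional[LoessBand]:
    """Locally weighted regression of M on A with a pointwise band.

    Fits a local polynomial (tricube weights over the ``span`` fraction of
    nearest neighbours) on a grid spanning the subset's A range.  The band
    is a normal-approximation pointwise interval: fit +- z * sigma * ||l||,
    with sigma estimated from the loess residuals at the data points.
    With fewer than ``min_points`` points a warning is raised and None is
    returned.
    """
    sub = records
    if class_subset is not None:
        if "class" not in records.columns:
            raise ValueError("records need a 'class' column to take a class subset")
        sub = records[records["class"].isin(class_subset)]
    sub = sub.dropna(subset=["M", "A"])
    n = len(sub)
    if n < min_points:
        warnings.warn(
            f"loess band needs at least {min_points} points, got {n}; band omitted",
            stacklevel=2,
        )
        return None
    x = sub["A"].to_numpy(float)
    y = sub["M"].to_numpy(float)
    k = max(degree + 2, int(np.ceil(span * n)))
    grid = np.linspace(x.min(), x.max(), n_grid)

    fit = np.empty(n_grid)
    lnorm = np.empty(n_grid)
    for i, g in enumerate(grid):
        fit[i], lnorm[i] = _local_poly_fit(x, y, g, k, degree)

    # residual scale from fits at the data points themselves
    yhat = np.array([_local_poly_fit(x, y, xi, k, degree)[0] for xi in x])
    dof = max(n - (degree + 1), 1)
    sigma = float(np.sqrt(np.sum((y - yhat) ** 2) / dof))
    z = stats.norm.ppf(0.5 + confidence / 2.0)
    half = z * sigma * lnorm
    return LoessBand(
        grid=grid,
        fit=fit,
        lower=fit - half,
        upper=fit + half,
        span=span,
        confidence=confidence,
    )
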