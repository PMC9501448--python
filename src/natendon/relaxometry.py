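"""Relaxation-time fitting.

Sodium T1 is fitted on ROI-mean saturation-recovery series

    S(TR) = S0 * (1 - exp(-TR/T1)) + offset,

sodium T2* on ROI-mean multi-echo series with the biexponential model of
spin-3/2 nuclei

    S(TE) = S0 * (ps * exp(-TE/T2s*) + (1-ps) * exp(-TE/T2l*)) + offset,

and proton T2* voxel-wise with a monoexponential plus offset.  ROI means are
used for the sodium fits because single sodium voxels are too noisy for
stable voxel-wise estimates.  All fits are bounded least squares with
deterministic multi-start initialization, so results are reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares

from .datamodel import LabelMap, RelaxationParams, Volume3D, same_grid

__all__ = [
    "FitResult",
    "roi_mean_series",
    "fit_t1_saturation_recovery",
    "fit_t2star_biexponential",
    "fit_t2star_mono",
    "fit_t2star_mono_map",
]

T1_BOUNDS_MS = (0.1, 500.0)
T2_BOUNDS_MS = (0.05, 200.0)
_LS_KW = dict(method="trf", xtol=1e-15, ftol=1e-15, gtol=1e-15, max_nfev=2000)


@dataclass
class FitResult:
    """Outcome of one relaxation fit.

    Only the parameters of the fitted model are set (``t1_ms`` for the
    saturation-recovery model; ``t2s_ms``/``t2l_ms``/``ps`` for the
    biexponential; ``t2s_ms`` alone for the monoexponential).  ``offset`` is
    the additive noise-floor term of the signal models.  ``degenerate`` marks
    non-identifiable fits (constant data; coincident T2* components).
    """

    s0: float = np.nan
    offset: float = np.nan
    t1_ms: float | None = None
    t2s_ms: float | None = None
    t2l_ms: float | None = None
    ps: float | None = None
    r_squared: float = np.nan
    sse: float = np.nan
    residuals: np.ndarray = field(default_factory=lambda: np.array([]))
    converged: bool = False
    degenerate: bool = False

    def relaxation(self, t1_ms: float | None = None) -> RelaxationParams:
        """Assemble a RelaxationParams (biexponential fit + external T1)."""
        t1 = self.t1_ms if t1_ms is None else t1_ms
        return RelaxationParams(t1, self.t2s_ms, self.t2l_ms, self.ps)


def _prepare(times_ms, signals, min_points: int):
    t = np.asarray(times_ms, dtype=float).ravel()
    y = np.asarray(signals, dtype=float).ravel()
    if t.size != y.size:
        raise ValueError("times and signals differ in length")
    if np.unique(t).size < min_points:
        raise ValueError(f"need at least {min_points} distinct time points, got {np.unique(t).size}")
    order = np.argsort(t)
    return t[order], y[order]


def _finish(result: FitResult, y: np.ndarray, model: np.ndarray) -> FitResult:
    res = y - model
    sst = float(((y - y.mean()) ** 2).sum())
    sse = float((res**2).sum())
    result.residuals = res
    result.sse = sse
    result.r_squared = 1.0 - sse / sst if sst > 0 else np.nan
    return result


def _is_constant(y: np.ndarray) -> bool:
    return np.ptp(y) <= 1e-12 * max(1.0, np.abs(y).max())



def _good_enough(sol, y: np.ndarray) -> bool:
    """Stop multi-start early once a start fits to numerical precision."""
    sst = float(((y - y.mean()) ** 2).sum())
    return 2.0 * sol.cost <= 1e-18 * max(sst, 1e-30)


def roi_mean_series(
    volumes: Sequence[Volume3D],
    mask: LabelMap,
    code: int,
    time_attr: str | None = None,
    valid: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """ROI-mean signal per volume, sorted by acquisition time.

    ``code`` may be one label code or a sequence (union ROI, e.g. the whole
    tendon).  ``time_attr`` is ``"tr_ms"`` or ``"te_ms"``; when omitted it is
    inferred as the one that varies across the series.  ``valid`` optionally
    excludes voxels (e.g. outside the sensitivity validity region).
    """
    if not volumes:
        raise ValueError("empty volume list")
    codes = [code] if np.isscalar(code) else list(code)
    roi = np.zeros(mask.shape, dtype=bool)
    for c in codes:
        roi |= mask.mask(c)
    for v in volumes:
        if not same_grid(v, mask):
            raise ValueError("volume and mask are on different grids")
    if valid is not None:
        roi = roi & valid
    if not roi.any():
        raise ValueError(f"ROI for code(s) {codes} is empty after exclusions")
    if time_attr is None:
        trs = {v.tr_ms for v in volumes}
        tes = {v.te_ms for v in volumes}
        time_attr = "tr_ms" if len(trs) > len(tes) else "te_ms"
    times = np.array([getattr(v, time_attr) for v in volumes], dtype=float)
    if np.any(~np.isfinite(times)):
        raise ValueError(f"volume missing {time_attr} metadata")
    means = np.array([float(v.data[roi].mean()) for v in volumes])
    order = np.argsort(times)
    return times[order], means[order]


def fit_t1_saturation_recovery(times_ms, signals) -> FitResult:
    """Fit {S0, T1, offset} to a saturation-recovery TR series."""
    t, y = _prepare(times_ms, signals, 3)
    if _is_constant(y):
        out = FitResult(s0=0.0, offset=float(y.mean()), degenerate=True)
        return _finish(out, y, np.full_like(y, y.mean()))

    def resid(p):
        s0, t1, off = p
        return s0 * (1.0 - np.exp(-t / t1)) + off - y

    s0_init = max(float(np.ptp(y)), 1e-12)
    # two-point log estimate of T1 from the first and last recovery points
    asym = float(y.max()) + 0.05 * s0_init
    ratios = np.clip(1.0 - (y - y.min()) / max(asym - y.min(), 1e-12), 1e-9, 1 - 1e-9)
    with np.errstate(divide="ignore"):
        t1_log = -t / np.log(ratios)
    t1_init = float(np.clip(np.median(t1_log[np.isfinite(t1_log) & (t1_log > 0)]), *T1_BOUNDS_MS)) \
        if np.any(np.isfinite(t1_log) & (t1_log > 0)) else 20.0
    lower = [0.0, T1_BOUNDS_MS[0], -np.inf]
    upper = [np.inf, T1_BOUNDS_MS[1], np.inf]
    best = None
    for t1_0 in dict.fromkeys([t1_init, 5.0, 20.0, 100.0]):
        sol = least_squares(
            resid, x0=[s0_init, t1_0, float(y.min())], bounds=(lower, upper), **_LS_KW
        )
        if best is None or sol.cost < best.cost:
            best = sol
        if _good_enough(best, y):
            break
    s0, t1, off = best.x
    out = FitResult(s0=float(s0), offset=float(off), t1_ms=float(t1), converged=bool(best.success))
    return _finish(out, y, resid(best.x) + y)


def fit_t2star_biexponential(times_ms, signals) -> FitResult:
    """Fit {S0, ps, T2s*, T2l*, offset} to a multi-echo decay.

    Bounded least squares with five deterministic starts; the component
    labels are ordered afterwards (T2s* <= T2l*), and coincident components
    (within 1e-3 ms) set the ``degenerate`` flag because ``ps`` is then
    unidentifiable.
    """
    t, y = _prepare(times_ms, signals, 5)
    if _is_constant(y):
        out = FitResult(s0=0.0, offset=float(y.mean()), degenerate=True)
        return _finish(out, y, np.full_like(y, y.mean()))

    def resid(p):
        s0, ps, t2s, t2l, off = p
        return s0 * (ps * np.exp(-t / t2s) + (1.0 - ps) * np.exp(-t / t2l)) + off - y

    s0_init = max(float(np.ptp(y)), 1e-12)
    off_init = float(y.min())
    eps = 1e-6
    lower = [0.0, eps, T2_BOUNDS_MS[0], T2_BOUNDS_MS[0], -np.inf]
    upper = [np.inf, 1.0 - eps, T2_BOUNDS_MS[1], T2_BOUNDS_MS[1], np.inf]
    starts = [
        (0.3, 1.0, 15.0),
        (0.3, 5.0, 15.0),
        (0.6, 1.0, 15.0),
        (0.6, 5.0, 15.0),
        (0.6, 6.0, 13.0),  # agarose-like single-pool start
    ]
    best = None
    for ps0, t2s0, t2l0 in starts:
        sol = least_squares(
            resid, x0=[s0_init, ps0, t2s0, t2l0, off_init], bounds=(lower, upper), **_LS_KW
        )
        if best is None or sol.cost < best.cost:
            best = sol
        if _good_enough(best, y):
            break
    s0, ps, t2s, t2l, off = best.x
    if t2s > t2l:  # undo label switching
        t2s, t2l, ps = t2l, t2s, 1.0 - ps
    degenerate = bool(abs(t2l - t2s) < 1e-3)
    model = resid(best.x) + y
    # A mono fit that explains the data equally well means ps is unidentifiable
    # (coincident components); report the common T2* in both slots.
    mono = fit_t2star_mono(t, y)
    sst = float(((y - y.mean()) ** 2).sum())
    if not degenerate and mono.sse <= 2.0 * best.cost * (1.0 + 1e-9) + 1e-12 * sst:
        degenerate = True
        s0, off = mono.s0, mono.offset
        t2s = t2l = float(mono.t2s_ms)
        model = y - mono.residuals
    out = FitResult(
        s0=float(s0),
        offset=float(off),
        t2s_ms=float(t2s),
        t2l_ms=float(t2l),
        ps=float(ps),
        converged=bool(best.success),
        degenerate=degenerate,
    )
    return _finish(out, y, model)


def fit_t2star_mono(times_ms, signals) -> FitResult:
    """Fit {S0, T2*, offset} to a monoexponential decay (proton T2*)."""
    t, y = _prepare(times_ms, signals, 3)
    if _is_constant(y):
        out = FitResult(s0=0.0, offset=float(y.mean()), degenerate=True)
        return _finish(out, y, np.full_like(y, y.mean()))

    def resid(p):
        s0, t2, off = p
        return s0 * np.exp(-t / t2) + off - y

    s0_init = max(float(np.ptp(y)), 1e-12)
    off_init = float(y.min())
    d = y[0] - off_init + 1e-12
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.clip((y[1] - off_init) / d, 1e-9, 1 - 1e-9)
        t2_init = float(np.clip((t[1] - t[0]) / -np.log(ratio), *T2_BOUNDS_MS))
    best = None
    for t2_0 in dict.fromkeys([t2_init, 2.0, 10.0]):
        sol = least_squares(
            resid,
            x0=[s0_init, t2_0, off_init],
            bounds=([0.0, T2_BOUNDS_MS[0], -np.inf], [np.inf, T2_BOUNDS_MS[1], np.inf]),
            **_LS_KW,
        )
        if best is None or sol.cost < best.cost:
            best = sol
        if _good_enough(best, y):
            break
    s0, t2, off = best.x
    out = FitResult(s0=float(s0), offset=float(off), t2s_ms=float(t2), converged=bool(best.success))
    return _finish(out, y, resid(best.x) + y)


def fit_t2star_mono_map(
    echo_volumes: Sequence[Volume3D],
    mask: LabelMap,
    codes: Sequence[int] | None = None,
) -> tuple[Volume3D, dict]:
    """Voxel-wise monoexponential T2* map inside a mask.

    Returns the map (zero outside the mask / failed voxels) and a QC dict with
    the fitted-voxel count, the failed-voxel count, and a boolean ``fitted``
    array marking voxels carrying a value.
    """
    if len(echo_volumes) < 3:
        raise ValueError("need at least 3 echo volumes")
    for v in echo_volumes:
        if not same_grid(v, mask):
            raise ValueError("echo volume and mask are on different grids")
    tes = np.array([v.te_ms for v in echo_volumes], dtype=float)
    if np.any(~np.isfinite(tes)):
        raise ValueError("echo volume missing te_ms metadata")
    order = np.argsort(tes)
    tes = tes[order]
    stack = np.stack([echo_volumes[i].data for i in order], axis=-1)
    if codes is None:
        codes = sorted(set(np.unique(mask.labels).tolist()) - {0})
    roi = np.isin(mask.labels, list(codes))
    t2_map = np.zeros(mask.shape)
    fitted = np.zeros(mask.shape, dtype=bool)
    n_failed = 0
    for idx in zip(*np.nonzero(roi)):
        fit = fit_t2star_mono(tes, stack[idx])
        if fit.degenerate or not np.isfinite(fit.t2s_ms or np.nan):
            n_failed += 1
            continue
        t2_map[idx] = fit.t2s_ms
        fitted[idx] = True
    ref = echo_volumes[0]
    vol = Volume3D(t2_map, ref.voxel_size_mm.copy(), ref.origin_mm.copy(), ref.nucleus)
    qc = {"n_fitted": int(fitted.sum()), "n_failed": int(n_failed), "fitted": fitted}
    return vol, qc
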