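"""Pixel-wise relaxometry: signal models, least-squares fitting, QC.

Three clinical quantitative-MRI sequences are supported, each with a
closed-form magnitude signal model in the acquisition variable ``t``:

* ``T2STAR`` — multi-gradient echo decay, ``S(TE) = A exp(-TE/T2*) [+ B]``
* ``T1RHO``  — spin-lock decay, ``S(T_SL) = A exp(-T_SL/T1rho) [+ B]``
* ``T1``     — inversion recovery,
  ``S(TI) = |A (1 - 2 exp(-TI/T1) + exp(-TR/T1))|``

``A`` is the signal amplitude and ``B`` an optional additive noise floor.
Inversion-recovery data are treated as magnitude images (the sign of the
recovering longitudinal magnetization is lost in clinical reconstruction),
so the model is fitted through a polarity fold with multi-start
initialization.

Per-pixel fits are scored with the adjusted coefficient of determination
and gated at a configurable quality-control threshold (default 0.95).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "AcquisitionProtocol",
    "PixelFit",
    "ParameterMap",
    "default_t1_protocol",
    "default_t1rho_protocol",
    "default_t2star_protocol",
    "filter_echoes",
    "fit_monoexp",
    "fit_ir",
    "adjusted_r2",
    "fit_map",
]

SequenceKind = Literal["T1", "T1RHO", "T2STAR"]

#: factor by which the fitted time constant may exceed the longest
#: acquisition time before the fit is flagged non-identifiable
TAU_CAP_FACTOR = 10.0


class ProtocolError(ValueError):
    """Invalid or insufficient acquisition protocol."""


@dataclass(frozen=True)
class AcquisitionProtocol:
    """Timing description of one quantitative MRI series.

    Parameters
    ----------
    kind:
        Sequence type: ``"T1"`` (inversion recovery, ``times_ms`` are
        inversion times), ``"T1RHO"`` (``times_ms`` are spin-lock
        durations) or ``"T2STAR"`` (``times_ms`` are echo times).
    times_ms:
        Strictly increasing, non-negative acquisition times in ms.
    tr_ms:
        Repetition time in ms; required for ``"T1"`` and must exceed the
        longest inversion time.
    """

    kind: SequenceKind
    times_ms: tuple[float, ...]
    tr_ms: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("T1", "T1RHO", "T2STAR"):
            raise ProtocolError(f"unknown sequence kind {self.kind!r}")
        t = np.asarray(self.times_ms, dtype=float)
        object.__setattr__(self, "times_ms", tuple(float(x) for x in t))
        if t.size < 2:
            raise ProtocolError("protocol needs at least two acquisition times")
        if np.any(t < 0) or np.any(np.diff(t) <= 0):
            raise ProtocolError("times must be non-negative and strictly increasing")
        if self.kind == "T1":
            if self.tr_ms is None or self.tr_ms <= t.max():
                raise ProtocolError("T1 protocol requires tr_ms > max(TI)")

    @property
    def times(self) -> np.ndarray:
        return np.asarray(self.times_ms, dtype=float)

    def __len__(self) -> int:
        return len(self.times_ms)


def default_t1_protocol() -> AcquisitionProtocol:
    """Inversion-recovery protocol: 7 TIs from 150 to 1500 ms, TR 3000 ms."""
    return AcquisitionProtocol(
        "T1", (150.0, 300.0, 500.0, 800.0, 1000.0, 1300.0, 1500.0), tr_ms=3000.0
    )


def default_t1rho_protocol() -> AcquisitionProtocol:
    """Spin-lock protocol: durations 0, 10, 20, 30, 40 ms."""
    return AcquisitionProtocol("T1RHO", (0.0, 10.0, 20.0, 30.0, 40.0))


def default_t2star_protocol() -> AcquisitionProtocol:
    """Multi-gradient-echo protocol: TE = 3.9 + n*6.9 ms, n = 0..14."""
    return AcquisitionProtocol("T2STAR", tuple(3.9 + 6.9 * n for n in range(15)))


def filter_echoes(
    protocol: AcquisitionProtocol, max_te_ms: float = 60.0
) -> AcquisitionProtocol:
    """Restrict a T2* protocol to echo times strictly below ``max_te_ms``.

    Long echoes of a gradient-echo train are dominated by noise-floor and
    susceptibility effects in cartilage, so they are excluded from the
    T2* fit. Raises :class:`ProtocolError` if fewer than three echoes
    survive.
    """
    if protocol.kind != "T2STAR":
        raise ProtocolError("echo filtering applies to T2STAR protocols only")
    kept = tuple(t for t in protocol.times_ms if t < max_te_ms)
    if len(kept) < 3:
        raise ProtocolError(
            f"only {len(kept)} echoes below {max_te_ms} ms; need at least 3"
        )
    if len(kept) == len(protocol.times_ms):
        return protocol
    return replace(protocol, times_ms=kept)


@dataclass
class PixelFit:
    """Result of one per-pixel model fit."""

    relax_ms: float
    amplitude: float
    noise_floor: float
    r2_adj: float
    converged: bool


def adjusted_r2(residuals: np.ndarray, signal: np.ndarray, n_params: int) -> float:
    """Coefficient of determination adjusted to the degrees of freedom.

    ``1 - (1 - R^2) (n - 1) / (n - p - 1)`` with ``R^2 = 1 - SSE/SST``.
    Returns NaN when the signal has zero total variance (undefined).
    """
    residuals = np.asarray(residuals, dtype=float)
    signal = np.asarray(signal, dtype=float)
    n = signal.size
    if n <= n_params + 1:
        raise ValueError("need more data points than parameters + 1")
    sst = float(np.sum((signal - signal.mean()) ** 2))
    if sst == 0.0:
        return float("nan")
    sse = float(np.sum(residuals**2))
    r2 = 1.0 - sse / sst
    return 1.0 - (1.0 - r2) * (n - 1) / (n - n_params - 1)


def _monoexp(t: np.ndarray, amp: float, tau: float, floor: float) -> np.ndarray:
    return amp * np.exp(-t / tau) + floor


def _loglin_tau0(signal: np.ndarray, times: np.ndarray, floor0: float) -> float:
    """Initial decay constant from log-linear regression of the offset signal."""
    s = signal - floor0
    good = s > 0
    if good.sum() >= 2:
        slope = np.polyfit(times[good], np.log(s[good]), 1)[0]
        if slope < 0:
            return float(-1.0 / slope)
    return float(np.ptp(times) / 2.0) or 1.0


def fit_monoexp(
    signal: np.ndarray,
    times: np.ndarray,
    fit_floor: bool = False,
) -> PixelFit:
    """Least-squares mono-exponential decay fit for T2* / T1rho data.

    Minimizes ``sum (signal - [A exp(-t/tau) + B])^2``; ``B`` is fixed at
    zero unless ``fit_floor`` is set. Optimizer failures and
    non-identifiable fits (decay constant at the cap, zero-variance
    signal) are reported with ``converged=False`` rather than raised.
    """
    signal = np.asarray(signal, dtype=float)
    times = np.asarray(times, dtype=float)
    if not np.all(np.isfinite(signal)):
        raise ValueError("signal contains non-finite values")
    n_params = 3 if fit_floor else 2
    if signal.size < n_params + 1:
        raise ValueError(f"need at least {n_params + 1} points")

    cap = TAU_CAP_FACTOR * float(times.max())
    amp0 = float(signal.max())
    floor0 = float(signal.min()) if fit_floor else 0.0
    tau0 = min(max(_loglin_tau0(signal, times, floor0), 1e-3), cap)
    if amp0 <= 0:
        amp0 = 1.0

    if fit_floor:

        def resid(p):
            return _monoexp(times, p[0], p[1], p[2]) - signal

        x0 = [amp0, tau0, floor0]
        lb, ub = [0.0, 1e-6, 0.0], [np.inf, cap, np.inf]
    else:

        def resid(p):
            return _monoexp(times, p[0], p[1], 0.0) - signal

        x0 = [amp0, tau0]
        lb, ub = [0.0, 1e-6], [np.inf, cap]

    try:
        res = least_squares(resid, x0, bounds=(lb, ub), xtol=1e-12, ftol=1e-12, gtol=1e-10)
    except Exception:
        return PixelFit(float("nan"), float("nan"), floor0, float("nan"), False)

    amp, tau = float(res.x[0]), float(res.x[1])
    floor = float(res.x[2]) if fit_floor else 0.0
    r2a = adjusted_r2(res.fun, signal, n_params)
    ok = bool(res.success) and tau < 0.999 * cap and np.isfinite(r2a)
    return PixelFit(tau, amp, floor, r2a, ok)


def _ir_model(ti: np.ndarray, amp: float, t1: float, tr: float) -> np.ndarray:
    return np.abs(amp * (1.0 - 2.0 * np.exp(-ti / t1) + np.exp(-tr / t1)))


def fit_ir(
    signal: np.ndarray,
    ti: np.ndarray,
    tr_ms: float,
    n_starts: int = 10,
) -> PixelFit:
    """Magnitude inversion-recovery T1 fit with multi-start initialization.

    The magnitude model ``|A (1 - 2 e^{-TI/T1} + e^{-TR/T1})|`` folds at
    the null point ``TI = T1 ln 2``, creating local minima on either side
    of the fold. A grid of ``n_starts`` log-spaced T1 seeds is scored
    cheaply (the amplitude that minimizes the SSE for a fixed T1 is a
    closed-form linear projection) and full nonlinear least squares is run
    from the two best seeds.
    """
    signal = np.asarray(signal, dtype=float)
    ti = np.asarray(ti, dtype=float)
    if not np.all(np.isfinite(signal)):
        raise ValueError("signal contains non-finite values")
    if signal.size < 4:
        raise ValueError("need at least 4 inversion times")

    cap = TAU_CAP_FACTOR * float(ti.max())
    seeds = np.geomspace(ti.min() / 2.0 if ti.min() > 0 else ti[1] / 2.0, 3.0 * ti.max(), n_starts)

    def seed_score(t1: float) -> tuple[float, float]:
        g = _ir_model(ti, 1.0, t1, tr_ms)
        denom = float(g @ g)
        a = float(g @ signal) / denom if denom > 0 else 0.0
        sse = float(np.sum((a * g - signal) ** 2))
        return sse, a

    scored = sorted((seed_score(t1) + (t1,) for t1 in seeds), key=lambda s: s[0])

    best = None
    for sse0, a0, t10 in scored[:2]:
        def resid(p):
            return _ir_model(ti, p[0], p[1], tr_ms) - signal

        try:
            res = least_squares(
                resid,
                [max(a0, 1e-6), t10],
                bounds=([0.0, 1e-6], [np.inf, cap]),
                xtol=1e-12,
                ftol=1e-12,
                gtol=1e-10,
            )
        except Exception:
            continue
        if best is None or res.cost < best.cost:
            best = res

    if best is None:
        return PixelFit(float("nan"), float("nan"), 0.0, float("nan"), False)
    amp, t1 = float(best.x[0]), float(best.x[1])
    r2a = adjusted_r2(best.fun, signal, 2)
    ok = bool(best.success) and t1 < 0.999 * cap and np.isfinite(r2a)
    return PixelFit(t1, amp, 0.0, r2a, ok)


@dataclass
class ParameterMap:
    """Fitted relaxation-parameter maps over a pixel mask.

    All arrays share the mask's 2-D shape; pixels outside the mask are
    NaN. ``qc_pass`` marks pixels whose adjusted R² met the QC threshold;
    downstream statistics must exclude pixels with ``qc_pass == False``.
    """

    kind: SequenceKind
    relax_ms: np.ndarray
    amplitude: np.ndarray
    noise_floor: np.ndarray
    r2_adj: np.ndarray
    converged: np.ndarray
    qc_pass: np.ndarray
    qc_threshold: float
    mask: np.ndarray = field(repr=False)

    @property
    def qc_pass_rate(self) -> float:
        m = self.mask.astype(bool)
        return float(self.qc_pass[m].mean()) if m.any() else float("nan")


def fit_map(
    stack,
    protocol: AcquisitionProtocol,
    qc: float = 0.95,
    fit_floor: bool = False,
) -> ParameterMap:
    """Fit every masked pixel of a signal stack with the matching model.

    ``stack`` is a :class:`~cartiqmap.phantom.SignalStack` or any object
    with ``data`` of shape ``(rows, cols, n_times)`` and a boolean
    ``mask``. Pixels with adjusted R² below ``qc`` are flagged as QC
    failures (kept in the map, excluded from statistics downstream).
    """
    data = np.asarray(stack.data, dtype=float)
    mask = np.asarray(stack.mask, dtype=bool)
    times = protocol.times
    if data.shape[-1] != times.size:
        raise ValueError(
            f"stack has {data.shape[-1]} acquisition points, protocol has {times.size}"
        )

    shape = mask.shape
    relax = np.full(shape, np.nan)
    amp = np.full(shape, np.nan)
    floor = np.full(shape, np.nan)
    r2a = np.full(shape, np.nan)
    conv = np.zeros(shape, dtype=bool)

    rows, cols = np.nonzero(mask)
    for r, c in zip(rows, cols):
        sig = data[r, c]
        if protocol.kind == "T1":
            pf = fit_ir(sig, times, protocol.tr_ms)
        else:
            pf = fit_monoexp(sig, times, fit_floor=fit_floor)
        relax[r, c] = pf.relax_ms
        amp[r, c] = pf.amplitude
        floor[r, c] = pf.noise_floor
        r2a[r, c] = pf.r2_adj
        conv[r, c] = pf.converged

    qc_pass = conv & (np.nan_to_num(r2a, nan=-np.inf) >= qc)
    return ParameterMap(
        kind=protocol.kind,
        relax_ms=relax,
        amplitude=amp,
        noise_floor=floor,
        r2_adj=r2a,
        converged=conv,
        qc_pass=qc_pass & mask,
        qc_threshold=qc,
        mask=mask,
    )
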