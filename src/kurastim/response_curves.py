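"""Block- and pulse-based amplitude/phase response curves and their statistics.

Block-based estimators contrast each stimulation on-epoch with its
preceding off-epoch:

* ARC: mean Hilbert envelope over the on-epoch minus the mean over the
  preceding off-epoch.
* PRC: a line is fitted to the unwrapped phase over the off-epoch and
  extrapolated to the end of the on-epoch; the gap between extrapolated and
  actual unwrapped phase, divided by the pulse count, is the per-pulse
  phase response.

Sign convention for the PRC
---------------------------
Two conventions are supported.  The default, ``"advance"``, reports the
actual per-pulse phase change ``(psi_actual - psi_predicted) / n_pulses``
(positive = stimulation advanced the phase).  This is the convention under
which the measured ARC is anticorrelated with the measured PRC derivative
for an oscillator population whose units respond as ``Z = -sin`` — the
relationship the pipeline is built to test.  ``"delay"`` returns the
negated value ``(psi_predicted - psi_actual) / n_pulses`` (positive =
stimulation delayed the phase) and flips the correlation sign.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats

from ._utils import wrap_phase
from .signal_processing import EDGE_TRIM_S, AnalyticBand, Recording, analytic, bandpass

__all__ = [
    "BlockResponse",
    "ResponseCurveSet",
    "RegressionLine",
    "AmplitudeDependence",
    "block_arc",
    "block_prc",
    "pulse_arc",
    "prc_derivative",
    "align_most_suppressive",
    "phase_dependence_anova",
    "arc_prc_correlation",
    "spearman_link",
    "block_amplitude_dependence",
    "analyze_trial",
    "curves_from_blocks",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class BlockResponse:
    """Estimates for one (off, on) block pair at one target phase."""

    target_phase: float
    arc_value: float
    prc_value: float
    n_pulses: int
    pre_stim_amp: float


@dataclass
class ResponseCurveSet:
    """ARC/PRC curves on the equally spaced target-phase grid."""

    phases: np.ndarray
    arc_mean: np.ndarray
    arc_sem: np.ndarray
    prc_mean: np.ndarray
    prc_sem: np.ndarray
    prc_derivative: np.ndarray
    alignment_offset: float = 0.0
    blocks: list = field(default_factory=list)

    def __post_init__(self):
        n = len(self.phases)
        for name in ("arc_mean", "arc_sem", "prc_mean", "prc_sem", "prc_derivative"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} length does not match phases")
        gaps = np.diff(np.sort(np.asarray(self.phases)))
        if n > 2 and not np.allclose(gaps, gaps[0], atol=1e-9):
            raise ValueError("phases must be equally spaced")


def _epoch_mean(x: np.ndarray, fs: float, start: float, stop: float) -> float:
    i0, i1 = int(np.ceil(start * fs)), int(np.floor(stop * fs))
    if i1 <= i0:
        raise ValueError("empty epoch window")
    return float(x[i0:i1].mean())


def _usable_interval(start, stop, duration, trim_s):
    lo = max(start, trim_s)
    hi = min(stop, duration - trim_s)
    return lo, hi


def block_arc(
    env: AnalyticBand,
    off_interval: tuple,
    on_interval: tuple,
    edge_trim_s: float = EDGE_TRIM_S,
    power: bool = False,
) -> float:
    """Mean envelope over the on-epoch minus the preceding off-epoch mean.

    ``power=True`` averages the squared envelope (band power) instead.
    """
    dur = env.envelope.size / env.fs
    x = env.envelope**2 if power else env.envelope
    off = _usable_interval(*off_interval, dur, edge_trim_s)
    on = _usable_interval(*on_interval, dur, edge_trim_s)
    if off[1] - off[0] < 1.0 or on[1] - on[0] < 1.0:
        raise ValueError("epochs must be at least 1 s after edge trimming")
    return _epoch_mean(x, env.fs, *on) - _epoch_mean(x, env.fs, *off)


def block_prc(
    env: AnalyticBand,
    off_interval: tuple,
    on_interval: tuple,
    n_pulses: int,
    edge_trim_s: float = EDGE_TRIM_S,
    convention: str = "advance",
) -> float:
    """Per-pulse phase response of one block (see module docstring for signs).

    Fits an ordinary least-squares line to the unwrapped phase over the
    off-epoch, extrapolates it to the end of the on-epoch to predict the
    phase under no stimulation, and normalises the prediction error by the
    pulse count.
    """
    if convention not in ("advance", "delay"):
        raise ValueError("convention must be 'advance' or 'delay'")
    if n_pulses <= 0:
        raise ValueError("block_prc undefined for n_pulses = 0")
    dur = env.envelope.size / env.fs
    fs = env.fs
    off = _usable_interval(*off_interval, dur, edge_trim_s)
    if off[1] - off[0] < 1.0:
        raise ValueError("off-epoch must be at least 1 s after edge trimming")
    i0, i1 = int(np.ceil(off[0] * fs)), int(np.floor(off[1] * fs))
    t_off = np.arange(i0, i1) / fs
    slope, intercept = np.polyfit(t_off, env.phase_unwrapped[i0:i1], 1)
    t_end = min(on_interval[1], dur - edge_trim_s)
    k_end = min(int(np.floor(t_end * fs)), env.phase_unwrapped.size - 1)
    psi_hat = slope * (k_end / fs) + intercept
    psi_actual = env.phase_unwrapped[k_end]
    value = (psi_actual - psi_hat) / n_pulses
    return value if convention == "advance" else -value


def pulse_arc(
    env: AnalyticBand,
    pulse_times: np.ndarray,
    window_ms: float = 10.0,
):
    """Per-pulse amplitude responses from short pre/post windows.

    Returns ``(pre_amp, delta_amp, overlap_flag)`` arrays: the mean envelope
    in the ``window_ms`` before each pulse, the post-window mean minus it,
    and whether the pulse's windows overlap a neighbouring pulse's.
    """
    pulse_times = np.asarray(pulse_times, dtype=float)
    w = window_ms * 1e-3
    fs = env.fs
    dur = env.envelope.size / fs
    pre = np.empty(pulse_times.size)
    delta = np.empty(pulse_times.size)
    keep = np.zeros(pulse_times.size, dtype=bool)
    for j, tp in enumerate(pulse_times):
        if tp - w < 0 or tp + w > dur:
            pre[j] = delta[j] = np.nan
            continue
        keep[j] = True
        pre[j] = _epoch_mean(env.envelope, fs, tp - w, tp)
        delta[j] = _epoch_mean(env.envelope, fs, tp, tp + w) - pre[j]
    overlap = np.zeros(pulse_times.size, dtype=bool)
    if pulse_times.size > 1:
        gaps = np.diff(pulse_times)
        overlap[:-1] |= gaps < 2 * w
        overlap[1:] |= gaps < 2 * w
    if overlap.any():
        log.info("pulse_arc: %d pulses have overlapping windows", int(overlap.sum()))
    return pre[keep], delta[keep], overlap[keep]


def prc_derivative(values: np.ndarray, dphi: float | None = None) -> np.ndarray:
    """Central difference on the circular target-phase grid."""
    v = np.asarray(values, dtype=float)
    if v.size < 3:
        raise ValueError("need at least 3 points for a central difference")
    if dphi is None:
        dphi = 2 * np.pi / v.size
    return (np.roll(v, -1) - np.roll(v, 1)) / (2.0 * dphi)


def align_most_suppressive(curves: ResponseCurveSet, reference_slot: int = 0) -> ResponseCurveSet:
    """Rotate the curves so the ARC minimum sits at ``reference_slot``.

    Ties in the minimum resolve to the smallest phase index (logged).
    """
    arc = np.asarray(curves.arc_mean)
    imin = int(np.argmin(arc))
    if (arc == arc[imin]).sum() > 1:
        log.info("align_most_suppressive: tie in ARC minimum, using smallest index")
    shift = reference_slot - imin
    rolled = {
        name: np.roll(np.asarray(getattr(curves, name)), shift)
        for name in ("arc_mean", "arc_sem", "prc_mean", "prc_sem", "prc_derivative")
    }
    offset = float(wrap_phase(curves.phases[imin] - curves.phases[reference_slot]))
    return replace(curves, alignment_offset=offset, **rolled)


def phase_dependence_anova(groups) -> float:
    """One-way ANOVA p-value for block responses grouped by target phase."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(g.size < 2 for g in groups):
        raise ValueError("need >= 2 groups with >= 2 blocks each")
    if all(np.ptp(g) == 0 for g in groups) and np.ptp(np.concatenate(groups)) == 0:
        raise ValueError("zero variance in all groups: F undefined")
    return float(stats.f_oneway(*groups).pvalue)


def arc_prc_correlation(arc_values, prc_derivative_values):
    """Pearson correlation between ARC and PRC-derivative samples."""
    a = np.asarray(arc_values, dtype=float)
    d = np.asarray(prc_derivative_values, dtype=float)
    if a.size != d.size or a.size < 3:
        raise ValueError("need matched vectors with n >= 3")
    if a.std() == 0 or d.std() == 0:
        raise ValueError("zero variance input")
    r, p = stats.pearsonr(a, d)
    return float(r), float(p)


def spearman_link(per_subject_r, per_subject_p):
    """Rank correlation between per-subject correlation strength and ANOVA p."""
    r, p = stats.spearmanr(per_subject_r, per_subject_p)
    return float(r), float(p)


@dataclass(frozen=True)
class RegressionLine:
    slope: float
    intercept: float
    p_value: float
    n: int


@dataclass
class AmplitudeDependence:
    """Per-condition regressions of block amplitude change on pre-stim amplitude."""

    lines: dict
    reference_subtracted: dict
    points: dict


def block_amplitude_dependence(blocks) -> AmplitudeDependence:
    """Regress block amplitude change on pre-stimulation amplitude per condition.

    ``blocks`` is an iterable of ``(pre_amp, arc_value, condition)`` with
    condition labels from ``{"reference", "suppressive", "amplifying"}``.
    Non-reference conditions additionally get a regression of their
    reference-line-subtracted values.
    """
    by_cond: dict[str, list] = {}
    for pre, val, cond in blocks:
        by_cond.setdefault(cond, []).append((float(pre), float(val)))
    lines, points = {}, {}
    for cond, pts in by_cond.items():
        if len(pts) < 5:
            warnings.warn(f"condition {cond!r} has < 5 blocks", stacklevel=2)
        x = np.array([p for p, _ in pts])
        y = np.array([v for _, v in pts])
        points[cond] = (x, y)
        if len(pts) >= 3 and x.std() > 0:
            res = stats.linregress(x, y)
            lines[cond] = RegressionLine(res.slope, res.intercept, res.pvalue, len(pts))
    ref_sub = {}
    ref = lines.get("reference")
    if ref is not None:
        for cond, (x, y) in points.items():
            if cond == "reference" or len(x) < 3 or x.std() == 0:
                continue
            resid = y - (ref.slope * x + ref.intercept)
            res = stats.linregress(x, resid)
            ref_sub[cond] = RegressionLine(res.slope, res.intercept, res.pvalue, len(x))
    return AmplitudeDependence(lines=lines, reference_subtracted=ref_sub, points=points)


# ---------------------------------------------------------------------------
# trial-level orchestration
# ---------------------------------------------------------------------------

def analyze_trial(
    rec: Recording,
    band=(20.0, 35.0),
    convention: str = "advance",
    edge_trim_s: float = EDGE_TRIM_S,
    power: bool = False,
) -> list[BlockResponse]:
    """Condition one trial recording and estimate every block's ARC and PRC.

    Pairs each on-epoch with its immediately preceding off-epoch; blocks
    with no usable off-epoch or zero pulses are skipped (logged).
    """
    env = analytic(bandpass(rec, band=band), band=band)
    out = []
    prev_off = None
    for ep in rec.epochs:
        if ep.label == "off":
            prev_off = ep
            continue
        if prev_off is None:
            log.info("skipping on-epoch at %.3f s with no preceding off-epoch", ep.start)
            continue
        n_pulses = int(
            np.sum((rec.pulse_times >= ep.start) & (rec.pulse_times < ep.stop))
        )
        off_iv = (prev_off.start, prev_off.stop)
        on_iv = (ep.start, ep.stop)
        try:
            arc = block_arc(env, off_iv, on_iv, edge_trim_s=edge_trim_s, power=power)
            pre_amp = _epoch_mean(
                env.envelope,
                env.fs,
                *_usable_interval(*off_iv, rec.duration, edge_trim_s),
            )
        except ValueError as exc:
            log.info("skipping block at %.3f s: %s", ep.start, exc)
            prev_off = None
            continue
        if n_pulses > 0:
            prc = block_prc(
                env, off_iv, on_iv, n_pulses, edge_trim_s=edge_trim_s,
                convention=convention,
            )
        else:
            log.info("block at %.3f s has no pulses; PRC undefined", ep.start)
            prc = np.nan
        target = ep.target_phase if ep.target_phase is not None else np.nan
        out.append(BlockResponse(target, arc, prc, n_pulses, pre_amp))
        prev_off = None
    return out


def curves_from_blocks(blocks) -> ResponseCurveSet:
    """Aggregate per-block estimates into mean +/- SEM curves per target phase."""
    blocks = list(blocks)
    phases = np.array(sorted({b.target_phase for b in blocks}))
    arc_mean = np.empty(phases.size)
    arc_sem = np.empty(phases.size)
    prc_mean = np.empty(phases.size)
    prc_sem = np.empty(phases.size)
    for i, ph in enumerate(phases):
        arc = np.array([b.arc_value for b in blocks if b.target_phase == ph])
        prc = np.array(
            [b.prc_value for b in blocks if b.target_phase == ph and np.isfinite(b.prc_value)]
        )
        arc_mean[i] = arc.mean()
        arc_sem[i] = arc.std(ddof=1) / np.sqrt(arc.size) if arc.size > 1 else np.nan
        prc_mean[i] = prc.mean() if prc.size else np.nan
        prc_sem[i] = prc.std(ddof=1) / np.sqrt(prc.size) if prc.size > 1 else np.nan
    return ResponseCurveSet(
        phases=phases,
        arc_mean=arc_mean,
        arc_sem=arc_sem,
        prc_mean=prc_mean,
        prc_sem=prc_sem,
        prc_derivative=prc_derivative(prc_mean),
        blocks=blocks,
    )
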