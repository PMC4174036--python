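"""Per-subject time-series conditioning.

Standard fMRI ROI-series conditioning applied independently to each subject's
segment: discard of initial volumes (scanner equilibration), linear
detrending, zero-phase band-pass filtering, nuisance regression against
motion/global/tissue signals, and standardization.  Default processing order
is discard -> detrend -> band-pass -> nuisance regression -> standardize.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
from scipy import signal as sps

from .roi_io import RoiTimeSeriesMatrix

log = logging.getLogger(__name__)

__all__ = [
    "NuisanceRegressors",
    "discard_initial_volumes",
    "detrend",
    "bandpass",
    "regress_nuisance",
    "standardize",
    "preprocess_pipeline",
]


@dataclass
class NuisanceRegressors:
    """Nuisance design for one subject: samples x k matrix plus names.

    Typical columns: six head-motion profiles, global signal, white-matter
    and CSF signals.
    """

    values: np.ndarray
    names: list[str]

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.values.ndim != 2:
            raise ValueError("regressors must be a 2-D matrix")
        if len(self.names) != self.values.shape[1]:
            raise ValueError("regressor names do not match columns")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite regressor values")


def discard_initial_volumes(ts: RoiTimeSeriesMatrix, k: int) -> RoiTimeSeriesMatrix:
    """Drop the first ``k`` rows of every subject segment."""
    if k < 0:
        raise ValueError("k must be >= 0")
    if k == 0:
        return replace(ts, values=ts.values.copy(), segment_bounds=list(ts.segment_bounds))
    blocks, bounds, pos = [], [], 0
    for sid, start, stop in ts.segment_bounds:
        if stop - start <= k:
            raise ValueError(
                f"segment {sid!r} has {stop - start} rows; cannot discard {k}"
            )
        block = ts.values[start + k : stop]
        blocks.append(block)
        bounds.append((sid, pos, pos + block.shape[0]))
        pos += block.shape[0]
    return replace(ts, values=np.vstack(blocks), segment_bounds=bounds)


def detrend(ts: RoiTimeSeriesMatrix) -> RoiTimeSeriesMatrix:
    """Remove the least-squares line (intercept + slope) per segment, per node."""
    for sid, start, stop in ts.segment_bounds:
        if stop - start < 3:
            raise ValueError(f"segment {sid!r} too short to detrend (< 3 rows)")

    def _detrend(sid, block):
        return sps.detrend(block, axis=0, type="linear")

    return ts.map_segments(_detrend)


def bandpass(
    ts: RoiTimeSeriesMatrix,
    low_hz: float = 0.01,
    high_hz: float = 0.08,
    order: int = 2,
) -> RoiTimeSeriesMatrix:
    """Zero-phase Butterworth band-pass per segment.

    The filter runs forward and backward (``filtfilt``) so in-band components
    keep their phase; segment edges are reflect-padded.  ``low_hz = 0`` gives
    a pure low-pass.
    """
    nyquist = 0.5 / ts.sampling_interval
    if not (0 <= low_hz < high_hz < nyquist):
        raise ValueError(
            f"cutoffs must satisfy 0 <= low < high < Nyquist ({nyquist:g} Hz); "
            f"got ({low_hz}, {high_hz})"
        )
    if low_hz == 0:
        b, a = sps.butter(order, high_hz / nyquist, btype="lowpass")
    else:
        b, a = sps.butter(
            order, [low_hz / nyquist, high_hz / nyquist], btype="bandpass"
        )
    ntaps = max(len(a), len(b))

    def _filt(sid, block):
        padlen = min(3 * ntaps, block.shape[0] - 1)
        return sps.filtfilt(b, a, block, axis=0, padtype="even", padlen=padlen)

    return ts.map_segments(_filt)


def regress_nuisance(
    ts: RoiTimeSeriesMatrix,
    regressors: dict[str, NuisanceRegressors] | NuisanceRegressors,
) -> RoiTimeSeriesMatrix:
    """Residualize every node on [intercept | nuisance regressors], per segment.

    ``regressors`` is either one design shared by all segments (single-subject
    use) or a mapping subject_id -> design.  Rank-deficient designs are solved
    minimum-norm (pseudo-inverse) with a logged warning; the residuals are the
    same as with any one copy of the duplicated columns.
    """

    def _design_for(sid, nrows):
        reg = regressors[sid] if isinstance(regressors, dict) else regressors
        if reg.values.shape[0] != nrows:
            raise ValueError(
                f"segment {sid!r}: {nrows} rows but {reg.values.shape[0]} regressor rows"
            )
        return np.column_stack([np.ones(nrows), reg.values])

    def _resid(sid, block):
        X = _design_for(sid, block.shape[0])
        rank = np.linalg.matrix_rank(X)
        if rank < X.shape[1]:
            log.warning(
                "segment %r: rank-deficient nuisance design (rank %d of %d); "
                "minimum-norm solution used",
                sid, rank, X.shape[1],
            )
        beta, *_ = np.linalg.lstsq(X, block, rcond=None)
        return block - X @ beta

    return ts.map_segments(_resid)


def standardize(ts: RoiTimeSeriesMatrix) -> RoiTimeSeriesMatrix:
    """Zero-mean, unit-variance (denominator m-1) per segment, per node."""

    def _std(sid, block):
        mu = block.mean(axis=0)
        sd = block.std(axis=0, ddof=1)
        zero = np.flatnonzero(sd <= 0)
        if zero.size:
            names = [ts.node_labels[j] for j in zero]
            raise ValueError(f"constant column(s) {names} in segment {sid!r}")
        return (block - mu) / sd

    return ts.map_segments(_std)


def _condition_regressors(
    regressors, do_detrend: bool, band, sampling_interval: float
):
    """Apply the data's detrend/band-pass to the nuisance design.

    Filtering the data but not the regressors would leave the filtered-out
    part of each confound in the data (the regression can only remove what is
    still collinear with the raw regressor), so the design must be
    conditioned identically.
    """

    def _one(reg: NuisanceRegressors) -> NuisanceRegressors:
        if reg.values.shape[1] == 0:
            return reg
        as_ts = RoiTimeSeriesMatrix(
            values=reg.values,
            node_labels=list(reg.names),
            sampling_interval=sampling_interval,
        )
        if do_detrend:
            as_ts = detrend(as_ts)
        if band is not None:
            as_ts = bandpass(as_ts, *band)
        return NuisanceRegressors(values=as_ts.values, names=list(reg.names))

    if isinstance(regressors, dict):
        return {sid: _one(reg) for sid, reg in regressors.items()}
    return _one(regressors)


def preprocess_pipeline(
    ts: RoiTimeSeriesMatrix,
    discard: int = 5,
    do_detrend: bool = True,
    band: tuple[float, float] | None = (0.01, 0.08),
    regressors: dict[str, NuisanceRegressors] | NuisanceRegressors | None = None,
    do_standardize: bool = True,
    condition_regressors: bool = True,
) -> RoiTimeSeriesMatrix:
    """Run the default conditioning chain; each stage logs its dimensions.

    ``regressors`` must match the post-discard row count.  By default the
    nuisance design is passed through the same detrend/band-pass as the data
    before the regression (``condition_regressors``).
    """
    out = discard_initial_volumes(ts, discard)
    log.info("discard %d: %d rows remain", discard, out.n_samples)
    if do_detrend:
        out = detrend(out)
        log.info("detrend: %d x %d", out.n_samples, out.n_nodes)
    if band is not None:
        out = bandpass(out, *band)
        log.info("bandpass %s Hz: %d x %d", band, out.n_samples, out.n_nodes)
    if regressors is not None:
        if condition_regressors:
            regressors = _condition_regressors(
                regressors, do_detrend, band, ts.sampling_interval
            )
        out = regress_nuisance(out, regressors)
        log.info("nuisance regression: %d x %d", out.n_samples, out.n_nodes)
    if do_standardize:
        out = standardize(out)
        log.info("standardize: %d x %d", out.n_samples, out.n_nodes)
    return out
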