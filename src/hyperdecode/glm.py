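"""Response-pattern estimation: HRF models, nuisance projection, GLM fitting.

Task time series are modeled with a canonical double-gamma hemodynamic
response convolved with a boxcar of the stimulus duration (1.6 s of active
stimulation per trial).  Each stimulus image is modeled separately within
each run; with the full layout of 10 runs x 2 familiarity conditions x 4
identities x 5 head views this yields 400 regressors of interest.  Button
presses, the repeated lead trial of each run, and per-run polynomial drift
terms are modeled as nuisance.  The per-regressor t-values — effect size
normalized by estimation uncertainty — are the multivariate features passed
to decoding.

Nuisance removal before the GLM (motion-like and physiological-like series
plus a discrete-cosine high-pass at 0.0066 Hz) is a single joint
least-squares projection, so the output is orthogonal to the entire removed
subspace in one operation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

from functools import lru_cache

import numpy as np
import pandas as pd
from scipy.linalg import qr
from scipy.stats import gamma as _gamma_dist


class RankError(ValueError):
    """Raised when a design (or nuisance basis) is rank-deficient."""


@dataclass(frozen=True)
class HRFSpec:
    """Canonical double-gamma hemodynamic response.

    The default parameters are the conventional ones: response peak at 6 s,
    undershoot peaking at 16 s with one sixth the amplitude, unit dispersions.
    ``duration`` is the boxcar length used for block convolution (the 1.6 s
    of active stimulation within a trial).
    """

    peak_delay: float = 6.0
    undershoot_delay: float = 16.0
    peak_dispersion: float = 1.0
    undershoot_dispersion: float = 1.0
    undershoot_ratio: float = 1.0 / 6.0
    duration: float = 1.6
    length: float = 32.0

    def __post_init__(self):
        if self.duration <= 0:
            raise ValueError("stimulus duration must be positive")

    def kernel(self, dt: float) -> np.ndarray:
        """Impulse response sampled every ``dt`` seconds, peak-normalized."""
        return _hrf_kernel(self, float(dt)).copy()

    def regressor(
        self,
        onsets: np.ndarray,
        durations: np.ndarray,
        amplitudes: np.ndarray,
        n_scans: int,
        tr: float,
        oversample: int = 10,
    ) -> np.ndarray:
        """HRF-convolved regressor sampled at scan times ``i * tr``.

        Events are laid out on an oversampled grid as boxcars of their
        duration (impulses when the duration is zero); overlapping
        contributions to the same regressor sum, with a warning when two
        events share an onset.
        """
        onsets = np.atleast_1d(np.asarray(onsets, dtype=float))
        durations = np.broadcast_to(
            np.asarray(durations, dtype=float), onsets.shape
        )
        amplitudes = np.broadcast_to(
            np.asarray(amplitudes, dtype=float), onsets.shape
        )
        if len(onsets) != len(set(np.round(onsets, 6))):
            warnings.warn("overlapping identical onsets; amplitudes summed")
        dt = tr / oversample
        grid = np.zeros(n_scans * oversample + int(self.length / dt) + 1)
        for onset, dur, amp in zip(onsets, durations, amplitudes):
            start = int(round(onset / dt))
            stop = max(start + 1, int(round((onset + dur) / dt)))
            if start < len(grid):
                grid[start : min(stop, len(grid))] += amp
        conv = np.convolve(grid, self.kernel(dt))[: n_scans * oversample]
        return conv[::oversample][:n_scans].copy()


@lru_cache(maxsize=32)
def _hrf_kernel(spec: HRFSpec, dt: float) -> np.ndarray:
    t = np.arange(0, spec.length, dt)
    peak = _gamma_dist.pdf(t, spec.peak_delay / spec.peak_dispersion,
                           scale=spec.peak_dispersion)
    under = _gamma_dist.pdf(t, spec.undershoot_delay / spec.undershoot_dispersion,
                            scale=spec.undershoot_dispersion)
    h = peak - spec.undershoot_ratio * under
    return h / h.max()


def dct_highpass_basis(n_scans: int, tr: float, cutoff_hz: float) -> np.ndarray:
    """Discrete-cosine columns with frequency at or below ``cutoff_hz``.

    Component ``m`` has frequency ``m / (2 * n_scans * tr)``; the constant
    term (m = 0) is always included, so projecting the basis out also
    demeans the data.
    """
    freqs = np.arange(n_scans) / (2.0 * n_scans * tr)
    n_comp = int(np.sum(freqs <= cutoff_hz))
    t = np.arange(n_scans)
    basis = np.cos(
        np.pi * np.outer(t + 0.5, np.arange(n_comp)) / n_scans
    )
    return basis


def project_out_nuisance(
    ts: np.ndarray,
    nuisance: np.ndarray = None,
    highpass_hz: float = 0.0066,
    tr: float = 1.25,
) -> np.ndarray:
    """Remove nuisance series and slow drift in a single joint projection.

    Parameters
    ----------
    ts : (n_nodes, n_time) array
    nuisance : (n_time, k) array or None
        Confound series (e.g. 6 motion-like + 6 physiological-like columns).
    highpass_hz : float
        Cosine components at or below this frequency are removed together
        with the nuisance columns (one combined least-squares projection).

    Returns the residual series, orthogonal to the removed subspace.
    """
    ts = np.asarray(ts, dtype=float)
    n_time = ts.shape[1]
    # constant + linear ramp + sub-cutoff cosines: polynomial drift up to
    # first order lies exactly in the removed subspace
    ramp = np.linspace(-1.0, 1.0, n_time)[:, None]
    cols = [dct_highpass_basis(n_time, tr, highpass_hz), ramp]
    if nuisance is not None:
        nuisance = np.asarray(nuisance, dtype=float)
        if nuisance.shape[0] != n_time:
            raise ValueError("nuisance rows must match time points")
        cols.append(nuisance)
    basis = np.column_stack(cols)
    if basis.shape[1] >= n_time:
        raise RankError(
            f"{basis.shape[1]} nuisance/drift columns for {n_time} time points"
        )
    coef, *_ = np.linalg.lstsq(basis, ts.T, rcond=None)
    return ts - (basis @ coef).T


@dataclass
class DesignMatrix:
    """Time x regressor matrix with machine-readable column metadata.

    ``columns`` is a DataFrame with one row per regressor: ``kind``
    ("interest", "response", "lead", "poly"), ``run``, ``familiarity``,
    ``label``, ``identity``, ``view``, ``order`` (polynomial order).
    """

    values: np.ndarray
    columns: pd.DataFrame
    tr: float

    @property
    def n_interest(self) -> int:
        return int((self.columns["kind"] == "interest").sum())

    @property
    def interest_idx(self) -> np.ndarray:
        return np.flatnonzero((self.columns["kind"] == "interest").to_numpy())

    def to_tsv(self, path, sidecar_path=None) -> None:
        pd.DataFrame(self.values).to_csv(path, sep="\t", index=False, header=False)
        if sidecar_path is not None:
            import json

            with open(sidecar_path, "w") as fh:
                json.dump(
                    {"tr": self.tr,
                     "columns": self.columns.to_dict(orient="records")},
                    fh, indent=1, default=str)


def _legendre_drift(n_scans: int, order: int) -> np.ndarray:
    x = np.linspace(-1.0, 1.0, n_scans)
    return np.column_stack([np.polynomial.legendre.Legendre.basis(k)(x)
                            for k in range(order + 1)])


def build_design(
    run_designs: list,
    hrf: HRFSpec = None,
    tr: float = 1.25,
    responses: dict = None,
    poly_order: int = 3,
    familiarities: list = None,
    n_views: int = 5,
) -> DesignMatrix:
    """Single design matrix over the concatenation of all runs.

    One regressor of interest per stimulus image per run; one regressor for
    button presses (events given per run index in ``responses``); one for
    the repeated lead trials pooled across runs; per-run polynomial drift up
    to ``poly_order``.  ``familiarities`` tags each run with its blocked
    familiarity condition (defaults to "task" for all runs).
    """
    if not run_designs:
        raise ValueError("run_designs must be nonempty")
    if tr <= 0:
        raise ValueError("TR must be positive")
    if poly_order < 0:
        raise ValueError("poly_order must be >= 0")
    if hrf is None:
        hrf = HRFSpec()
    if familiarities is None:
        familiarities = ["task"] * len(run_designs)
    if len(familiarities) != len(run_designs):
        raise ValueError("one familiarity tag per run required")

    scans = [run.n_scans(tr) for run in run_designs]
    total = int(np.sum(scans))
    offsets = np.r_[0, np.cumsum(scans)]

    interest_cols, interest_meta = [], []
    lead_col = np.zeros(total)
    resp_col = np.zeros(total)
    for r, (run, fam) in enumerate(zip(run_designs, familiarities)):
        sl = slice(offsets[r], offsets[r + 1])
        by_label = {}
        for t in run.trials:
            if t.is_lead:
                lead_col[sl] += hrf.regressor(
                    [t.onset], [hrf.duration], [1.0], scans[r], tr)
                continue
            if t.is_null:
                continue
            by_label.setdefault(t.label, []).append(t.onset)
        for label in sorted(by_label):
            col = np.zeros(total)
            ons = by_label[label]
            col[sl] = hrf.regressor(
                ons, np.full(len(ons), hrf.duration), np.ones(len(ons)),
                scans[r], tr)
            if not np.any(col):
                raise ValueError(
                    f"all-zero regressor for image {label} in run {r}")
            interest_cols.append(col)
            interest_meta.append(
                {"kind": "interest", "run": r, "familiarity": fam,
                 "label": label, "identity": label // n_views,
                 "view": label % n_views, "order": -1})
        if responses and r in responses and len(responses[r]):
            ons = np.asarray(responses[r], dtype=float)
            resp_col[sl] += hrf.regressor(
                ons, np.zeros(len(ons)), np.ones(len(ons)), scans[r], tr)

    cols = interest_cols
    meta = list(interest_meta)
    if np.any(resp_col):
        cols = cols + [resp_col]
        meta.append({"kind": "response", "run": -1, "familiarity": "",
                     "label": -1, "identity": -1, "view": -1, "order": -1})
    cols = cols + [lead_col]
    meta.append({"kind": "lead", "run": -1, "familiarity": "", "label": -1,
                 "identity": -1, "view": -1, "order": -1})
    for r in range(len(run_designs)):
        drift = _legendre_drift(scans[r], poly_order)
        for k in range(drift.shape[1]):
            col = np.zeros(total)
            col[offsets[r]: offsets[r + 1]] = drift[:, k]
            cols.append(col)
            meta.append({"kind": "poly", "run": r, "familiarity": "",
                         "label": -1, "identity": -1, "view": -1, "order": k})
    return DesignMatrix(np.column_stack(cols), pd.DataFrame(meta), tr)


@dataclass
class PatternSet:
    """Per-condition response patterns (t-values) with sample metadata.

    ``data`` is (n_samples, n_nodes); ``meta`` has one row per sample with
    ``familiarity``, ``run``, ``identity``, ``view``.  ``betas`` carries the
    raw effect estimates alongside the t-values.
    """

    data: np.ndarray
    meta: pd.DataFrame
    betas: np.ndarray = None
    statistic: str = "t"

    def select(self, familiarity: str) -> "PatternSet":
        mask = (self.meta["familiarity"] == familiarity).to_numpy()
        return PatternSet(
            self.data[mask],
            self.meta.loc[mask].reset_index(drop=True),
            None if self.betas is None else self.betas[mask],
            self.statistic,
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.data)
        df.index = pd.MultiIndex.from_frame(
            self.meta[["familiarity", "run", "identity", "view"]]
        )
        return df

    def save_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t")


def _collinear_columns(X: np.ndarray) -> list:
    """Columns beyond the numerical rank, identified by pivoted QR."""
    _, R, piv = qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps
    rank = int((diag > tol).sum())
    return sorted(int(c) for c in piv[rank:])


def fit_glm(ts: np.ndarray, design: DesignMatrix) -> PatternSet:
    """Ordinary least squares over all regressors; package t-values of the
    regressors of interest.

    ``ts`` is (n_nodes, n_time).  t = beta / SE with residual degrees of
    freedom ``n_time - n_regressors``.  A rank-deficient design raises
    :class:`RankError` naming the collinear columns.
    """
    ts = np.asarray(ts, dtype=float)
    X = design.values
    n_time, p = X.shape
    if ts.shape[1] != n_time:
        raise ValueError("time axis mismatch between data and design")
    if np.linalg.matrix_rank(X) < p:
        raise RankError(
            f"design is rank-deficient; collinear columns: "
            f"{_collinear_columns(X)}"
        )
    Y = ts.T  # time x nodes
    xtx = X.T @ X
    xtx_inv = np.linalg.inv(xtx)
    beta = xtx_inv @ (X.T @ Y)  # p x nodes
    resid = Y - X @ beta
    dof = n_time - p
    sigma2 = (resid**2).sum(axis=0) / dof  # per node
    se = np.sqrt(np.outer(np.diag(xtx_inv), sigma2))
    with np.errstate(divide="ignore", invalid="ignore"):
        tvals = np.where(se > 0, beta / se, 0.0)
    idx = design.interest_idx
    meta = (
        design.columns.iloc[idx][["familiarity", "run", "identity", "view"]]
        .reset_index(drop=True)
    )
    return PatternSet(tvals[idx], meta, betas=beta[idx], statistic="t")
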