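"""Frequency-recognition scorers: CCA, filter-bank CCA, MSI and MEC.

Each scorer maps an EEG window (``channels x samples``) and a target's
harmonic reference matrix to a scalar score; classification is the argmax of
the score over targets.  The four methods quantify different things:

* **CCA** -- the largest canonical correlation between linear combinations of
  the channels and linear combinations of the sin/cos references.
* **FBCCA** -- CCA applied to a bank of sub-band-filtered copies of the EEG,
  combined as ``sum_i (i**-a + b) * rho_i**2``.
* **MSI** -- the S-estimator: one minus the normalized eigenvalue entropy of
  the whitened joint correlation matrix of ``[EEG; reference]``.  1 means
  perfect synchronization, 0 statistical independence.
* **MEC** -- minimum energy combination: spatial filters that minimize the
  energy left after projecting out the reference subspace, followed by an
  SNR-like test statistic in which the noise floor at each harmonic comes
  from an autoregressive (Burg) spectrum fit to the residual signals.

Besides the scalar per-target functions, the module provides prepared
scorers (:func:`prepare_scorer`) that factor every per-window quantity out
of the per-channel-subset inner loop.  Canonical correlations of a channel
subset ``s`` only need the Gram blocks ``Cyy[s, s]`` and ``A[s] = (Y Q_x)[s]``
with ``Q_x`` an orthonormal reference basis, so scoring thousands of random
subsets against 40 targets reduces to small Cholesky/eigen problems.  The
voting ensemble is built on this fast path; the scalar functions double as
the slow reference path in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy import linalg as sla

from .signal_model import (
    BandSpec,
    ReferenceSet,
    StimulusGrid,
    bandpass_array,
    build_reference_set,
)

__all__ = [
    "MethodSpec",
    "FilterBankSpec",
    "score_cca",
    "score_fbcca",
    "score_msi",
    "score_mec",
    "classify_single",
    "prepare_scorer",
    "burg",
    "RIDGE_SCALE",
    "MEC_RESIDUAL_ENERGY",
    "MEC_T_CAP",
]

#: Relative ridge added to channel covariance/correlation blocks before
#: whitening: ``eps = RIDGE_SCALE * trace(C) / dim``.
RIDGE_SCALE = 1e-8

#: MEC keeps the smallest-eigenvalue spatial filters whose cumulative share
#: of residual energy stays at or below this fraction (never fewer than one).
MEC_RESIDUAL_ENERGY = 0.10

#: MEC score returned when the residual is numerically zero (noiseless data).
MEC_T_CAP = 1e9


# ---------------------------------------------------------------------------
# method specifications


@dataclass(frozen=True)
class FilterBankSpec:
    """FBCCA sub-band layout and weight law ``w(i) = i**-a + b``.

    Default sub-bands span ``[8*i, 88]`` Hz for ``i = 1..7`` with
    ``a = 1.25, b = 0.25``.
    """

    n_subbands: int = 7
    a: float = 1.25
    b: float = 0.25
    subband_high: float = 88.0
    subband_low_step: float = 8.0

    def __post_init__(self):
        if self.n_subbands < 1:
            raise ValueError("need at least one sub-band")
        w = self.weights
        if np.any(w <= 0) or np.any(np.diff(w) > 0):
            raise ValueError("sub-band weights must be positive, non-increasing")

    @property
    def weights(self) -> np.ndarray:
        i = np.arange(1, self.n_subbands + 1, dtype=float)
        return i ** (-self.a) + self.b

    def bands(self) -> Tuple[BandSpec, ...]:
        return tuple(
            BandSpec(self.subband_low_step * i, self.subband_high)
            for i in range(1, self.n_subbands + 1)
        )


@dataclass(frozen=True)
class MethodSpec:
    """A named scorer plus its parameters.

    Defaults follow the standard parameterizations of each method: MEC with
    3 harmonics and an order-15 Burg AR noise model on detrended, unfiltered
    signals; MSI with 3 harmonics on a [0.5, 50] Hz band; FBCCA with 5
    harmonics and a 7-sub-band bank weighted by ``i**-1.25 + 0.25``.
    """

    name: str
    Nh: int = 3
    band: Optional[BandSpec] = None
    ar_order: Optional[int] = None
    filterbank: Optional[FilterBankSpec] = None

    def __post_init__(self):
        if self.name not in {"MEC", "MSI", "CCA", "FBCCA"}:
            raise ValueError(f"unknown method {self.name!r}")
        if self.name == "MEC" and (self.ar_order is None or self.ar_order < 1):
            raise ValueError("MEC requires ar_order >= 1")
        if self.name == "FBCCA" and self.filterbank is None:
            raise ValueError("FBCCA requires a FilterBankSpec")
        if self.name != "MEC" and self.ar_order is not None:
            raise ValueError("ar_order only applies to MEC")
        if self.name != "FBCCA" and self.filterbank is not None:
            raise ValueError("filterbank only applies to FBCCA")

    @staticmethod
    def mec(Nh: int = 3, ar_order: int = 15) -> "MethodSpec":
        return MethodSpec(name="MEC", Nh=Nh, ar_order=ar_order)

    @staticmethod
    def msi(Nh: int = 3, band: BandSpec = BandSpec(0.5, 50.0)) -> "MethodSpec":
        return MethodSpec(name="MSI", Nh=Nh, band=band)

    @staticmethod
    def cca(Nh: int = 3, band: Optional[BandSpec] = None) -> "MethodSpec":
        return MethodSpec(name="CCA", Nh=Nh, band=band)

    @staticmethod
    def fbcca(
        Nh: int = 5, filterbank: FilterBankSpec = FilterBankSpec()
    ) -> "MethodSpec":
        return MethodSpec(name="FBCCA", Nh=Nh, filterbank=filterbank)

    @staticmethod
    def from_name(name: str) -> "MethodSpec":
        factories = {
            "MEC": MethodSpec.mec,
            "MSI": MethodSpec.msi,
            "CCA": MethodSpec.cca,
            "FBCCA": MethodSpec.fbcca,
        }
        key = name.upper()
        if key not in factories:
            raise ValueError(f"unknown method {name!r}")
        return factories[key]()


# ---------------------------------------------------------------------------
# shared linear-algebra helpers


def _ridge_eps(C: np.ndarray) -> float:
    return RIDGE_SCALE * float(np.trace(C)) / C.shape[0]


def _center(Y: np.ndarray) -> np.ndarray:
    Y = np.asarray(Y, dtype=float)
    return Y - Y.mean(axis=-1, keepdims=True)


def _canonical_corrs_sq(Y: np.ndarray, R: np.ndarray) -> np.ndarray:
    """Squared canonical correlations between rows of ``Y`` and rows of ``R``.

    ``Y`` is centered ``channels x samples``; ``R`` is a reference matrix.
    Returns the squared correlations in descending order, clipped to [0, 1].
    """
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    R = np.atleast_2d(np.asarray(R, dtype=float))
    if Y.shape[1] != R.shape[1]:
        raise ValueError("window and reference must share the sample axis")
    Qx, _ = np.linalg.qr(R.T)
    A = Y @ Qx
    Cyy = Y @ Y.T
    Cyy[np.diag_indices_from(Cyy)] += _ridge_eps(Cyy)
    L = np.linalg.cholesky(Cyy)
    B = sla.solve_triangular(L, A, lower=True)
    ev = np.linalg.eigvalsh(B.T @ B)[::-1]
    return np.clip(ev, 0.0, 1.0)


def _msi_from_sigmas(sigma: np.ndarray, P: int) -> float:
    """S-estimator from the singular values of the whitened cross block.

    The whitened joint correlation matrix of dimension ``P`` has eigenvalues
    ``1 +/- sigma_k`` plus ones; ``S = 1 + sum(lam_bar log lam_bar) / log P``.
    """
    sigma = np.clip(np.asarray(sigma, dtype=float), 0.0, 1.0)
    lam = np.concatenate([1.0 + sigma, 1.0 - sigma, np.ones(P - 2 * sigma.size)])
    lam_bar = lam / P
    ent = np.where(lam_bar > 0, lam_bar * np.log(np.maximum(lam_bar, 1e-300)), 0.0)
    return float(1.0 + ent.sum() / np.log(P))


def _standardize_rows(X: np.ndarray) -> np.ndarray:
    """Rows scaled to zero mean, unit Euclidean norm (correlation geometry)."""
    X = _center(np.atleast_2d(X))
    nrm = np.linalg.norm(X, axis=1, keepdims=True)
    nrm[nrm == 0] = 1.0
    return X / nrm


# ---------------------------------------------------------------------------
# scalar per-target scorers (reference path)


def score_cca(window: np.ndarray, reference: np.ndarray) -> float:
    """Largest canonical correlation between EEG channels and references."""
    rho2 = _canonical_corrs_sq(_center(window), reference)
    return float(np.sqrt(rho2[0]))


def score_fbcca(
    window: np.ndarray,
    reference: np.ndarray,
    fb: FilterBankSpec,
    fs: float,
) -> float:
    """Weighted sub-band CCA score ``sum_i w(i) * rho_i**2``.

    Only the EEG is sub-band filtered; the sinusoidal references are used
    unmodified in every sub-band.
    """
    total = 0.0
    for i, (w, band) in enumerate(zip(fb.weights, fb.bands()), start=1):
        try:
            sub = bandpass_array(window, band, fs)
            rho2 = _canonical_corrs_sq(_center(sub), reference)[0]
        except Exception as exc:  # attach the sub-band index for diagnosis
            raise RuntimeError(f"FBCCA sub-band {i} failed: {exc}") from exc
        total += w * rho2
    return float(total)


def score_msi(window: np.ndarray, reference: np.ndarray) -> float:
    """Synchronization index S between EEG channels and a reference matrix."""
    Yn = _standardize_rows(window)
    Xn = _standardize_rows(reference)
    # singular values of C11^-1/2 C12 C22^-1/2 == canonical correlations of
    # the standardized rows; computed through the shared Cholesky machinery.
    C22 = Xn @ Xn.T
    C22[np.diag_indices_from(C22)] += _ridge_eps(C22)
    w, V = np.linalg.eigh(C22)
    W = V @ np.diag(1.0 / np.sqrt(w)) @ V.T
    A = Yn @ (Xn.T @ W)
    C11 = Yn @ Yn.T
    C11[np.diag_indices_from(C11)] += _ridge_eps(C11)
    L = np.linalg.cholesky(C11)
    B = sla.solve_triangular(L, A, lower=True)
    m = min(Yn.shape[0], Xn.shape[0])
    ev = np.sort(np.linalg.eigvalsh(B.T @ B))[::-1][:m]
    sigma = np.sqrt(np.clip(ev, 0.0, 1.0))
    return _msi_from_sigmas(sigma, Yn.shape[0] + Xn.shape[0])


def burg(x: np.ndarray, order: int) -> Tuple[np.ndarray, np.ndarray]:
    """Batched Burg AR estimation.

    ``x`` is ``(batch, samples)`` (a single signal may be 1-D).  Returns
    ``(a, sigma2)`` with ``a`` of shape ``(batch, order)`` such that
    ``x_t = sum_m a_m x_{t-m} + e_t`` and ``sigma2`` the innovation variance,
    matching the convention of ``statsmodels.regression.linear_model.burg``.
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    nb, n = x.shape
    if order < 1 or order >= n:
        raise ValueError("order must satisfy 1 <= order < n_samples")
    f = x[:, 1:].copy()
    b = x[:, :-1].copy()
    a = np.zeros((nb, order))
    E = np.mean(x * x, axis=1)
    for m in range(order):
        num = 2.0 * np.einsum("ij,ij->i", f, b)
        den = np.einsum("ij,ij->i", f, f) + np.einsum("ij,ij->i", b, b)
        k = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
        if m > 0:
            a[:, :m] = a[:, :m] - k[:, None] * a[:, m - 1 :: -1]
        a[:, m] = k
        E = E * (1.0 - k * k)
        if m < order - 1:
            f_new = f[:, 1:] - k[:, None] * b[:, 1:]
            b = b[:, :-1] - k[:, None] * f[:, :-1]
            f = f_new
    return a, E


def _ar_psd(a: np.ndarray, sigma2: np.ndarray, omega: np.ndarray) -> np.ndarray:
    """AR power spectral density at angular frequencies ``omega`` (rad/sample).

    ``a`` is ``(batch, order)``, ``omega`` ``(batch, H)``; returns
    ``sigma2 / |1 - sum_m a_m e^{-i omega m}|**2`` per signal and frequency.
    """
    order = a.shape[1]
    m = np.arange(1, order + 1)
    e = np.exp(-1j * omega[..., None] * m)  # (batch, H, order)
    den = np.abs(1.0 - np.einsum("bm,bhm->bh", a.astype(complex), e)) ** 2
    return sigma2[:, None] / np.maximum(den, 1e-30)


def _mec_select(lam: np.ndarray) -> int:
    """Number of minimum-energy filters kept by the 10% residual-energy rule."""
    lam = np.clip(lam, 0.0, None)
    tot = lam.sum()
    if tot <= 0:
        return 1
    ns = int(np.count_nonzero(np.cumsum(lam) / tot <= MEC_RESIDUAL_ENERGY))
    return max(ns, 1)


def score_mec(
    window: np.ndarray,
    reference: np.ndarray,
    fs: float,
    harmonic_freqs: Sequence[float],
    ar_order: int = 15,
) -> float:
    """Minimum-energy-combination SNR statistic for one target.

    ``reference`` rows must be the sin/cos pair per harmonic, in the order of
    ``harmonic_freqs`` (Hz).  Steps: project the reference subspace out of the
    (detrended) channels; eigen-decompose the residual energy and keep the
    smallest-eigenvalue combinations holding <= 10% of it (at least one),
    weighted by ``1/sqrt(lambda)``; measure signal power of each virtual
    channel at every harmonic and divide by an AR(``ar_order``) noise floor
    fit to the residual virtual channels; average the ratios.
    """
    Y = _center(window)
    harmonic_freqs = np.asarray(harmonic_freqs, dtype=float)
    X = np.asarray(reference, dtype=float).T  # samples x 2Nh
    if X.shape[0] != Y.shape[1]:
        raise ValueError("window and reference must share the sample axis")
    if X.shape[1] != 2 * harmonic_freqs.size:
        raise ValueError("reference must hold one sin/cos pair per harmonic")
    Qx, _ = np.linalg.qr(X)
    A = Y @ Qx
    resid_gram = Y @ Y.T - A @ A.T
    lam, vec = np.linalg.eigh(resid_gram)
    if lam[-1] <= 1e-12 * max(1.0, float(np.trace(Y @ Y.T))):
        return MEC_T_CAP
    ns = _mec_select(lam)
    lam_kept = np.maximum(lam[:ns], 1e-12 * max(lam[-1], 1e-30))
    Wmat = vec[:, :ns] / np.sqrt(lam_kept)
    S_virt = Y.T @ Wmat  # samples x ns
    resid_virt = S_virt - Qx @ (Qx.T @ S_virt)
    a, sigma2 = burg(resid_virt.T, ar_order)
    omega = 2.0 * np.pi * harmonic_freqs / fs
    psd = _ar_psd(a, sigma2, np.broadcast_to(omega, (ns, omega.size)))
    n = Y.shape[1]
    noise = np.maximum(n * psd, 1e-30)  # expected |X_h^T noise|^2 power
    proj = X.T @ S_virt  # 2Nh x ns
    power = proj[0::2] ** 2 + proj[1::2] ** 2  # Nh x ns
    return float(np.mean(power.T / noise))


# ---------------------------------------------------------------------------
# prepared (batched) scorers


class _Prepared:
    """Per-window state of one scorer; ``scores(idx)`` rates all targets for
    the channel subset given by row indices ``idx``."""

    n_targets: int

    def scores(self, idx: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def classify(self, idx: np.ndarray) -> int:
        return int(np.argmax(self.scores(idx)))


def _stack_projections(Y: np.ndarray, refs: ReferenceSet) -> np.ndarray:
    """``A[n] = Y @ orth(refs[n].T)`` stacked over targets: (N, C, 2Nh)."""
    mats = []
    for R in refs.targets:
        Qx, _ = np.linalg.qr(R.T)
        mats.append(Y @ Qx)
    return np.stack(mats)


def _subset_sq_corrs(Cyy: np.ndarray, A: np.ndarray, idx: np.ndarray) -> np.ndarray:
    """Squared canonical correlations per target for one channel subset.

    ``Cyy`` is the ridged full-pool Gram, ``A`` the stacked (N, C, m)
    reference projections.  Returns (N, m) eigenvalues in ascending order.
    """
    Cs = Cyy[np.ix_(idx, idx)]
    L = np.linalg.cholesky(Cs)
    As = A[:, idx, :]
    N, ns, m = As.shape
    flat = As.transpose(1, 0, 2).reshape(ns, N * m)
    B = sla.solve_triangular(L, flat, lower=True).reshape(ns, N, m).transpose(1, 0, 2)
    G = np.einsum("nsi,nsj->nij", B, B)
    return np.clip(np.linalg.eigvalsh(G), 0.0, 1.0)


class _PreparedCCA(_Prepared):
    def __init__(self, window, fs, grid, Nh, band):
        Y = window if band is None else bandpass_array(window, band, fs)
        self.Y = _center(Y)
        refs = build_reference_set(grid, Nh, fs, self.Y.shape[1])
        self.A = _stack_projections(self.Y, refs)
        Cyy = self.Y @ self.Y.T
        Cyy[np.diag_indices_from(Cyy)] += _ridge_eps(Cyy)
        self.Cyy = Cyy
        self.n_targets = grid.n_targets

    def scores(self, idx):
        ev = _subset_sq_corrs(self.Cyy, self.A, idx)
        return np.sqrt(ev[:, -1])


class _PreparedFBCCA(_Prepared):
    def __init__(self, window, fs, grid, Nh, fb: FilterBankSpec):
        refs = build_reference_set(grid, Nh, fs, window.shape[1])
        self.weights = fb.weights
        self.blocks = []
        for band in fb.bands():
            Yb = _center(bandpass_array(window, band, fs))
            Cyy = Yb @ Yb.T
            Cyy[np.diag_indices_from(Cyy)] += _ridge_eps(Cyy)
            self.blocks.append((Cyy, _stack_projections(Yb, refs)))
        self.n_targets = grid.n_targets

    def scores(self, idx):
        total = np.zeros(self.n_targets)
        for w, (Cyy, A) in zip(self.weights, self.blocks):
            total += w * _subset_sq_corrs(Cyy, A, idx)[:, -1]
        return total


class _PreparedMSI(_Prepared):
    def __init__(self, window, fs, grid, Nh, band):
        Y = window if band is None else bandpass_array(window, band, fs)
        self.Yn = _standardize_rows(Y)
        refs = build_reference_set(grid, Nh, fs, self.Yn.shape[1])
        self.m_ref = 2 * Nh
        mats = []
        for R in refs.targets:
            Xn = _standardize_rows(R)
            C22 = Xn @ Xn.T
            C22[np.diag_indices_from(C22)] += _ridge_eps(C22)
            w, V = np.linalg.eigh(C22)
            W = V @ np.diag(1.0 / np.sqrt(w)) @ V.T
            mats.append(self.Yn @ (Xn.T @ W))
        self.A = np.stack(mats)
        C11 = self.Yn @ self.Yn.T
        C11[np.diag_indices_from(C11)] += _ridge_eps(C11)
        self.C11 = C11
        self.n_targets = grid.n_targets

    def scores(self, idx):
        ev = _subset_sq_corrs(self.C11, self.A, idx)
        ns = idx.size
        m = min(ns, self.m_ref)
        P = ns + self.m_ref
        out = np.empty(self.n_targets)
        for n in range(self.n_targets):
            sigma = np.sqrt(ev[n, ::-1][:m])
            out[n] = _msi_from_sigmas(sigma, P)
        return out


class _PreparedMEC(_Prepared):
    def __init__(self, window, fs, grid, Nh, ar_order):
        self.Y = _center(window)  # MEC runs on detrended, unfiltered signals
        n = self.Y.shape[1]
        refs = build_reference_set(grid, Nh, fs, n)
        self.Qx = []  # orthonormal reference bases, samples x 2Nh
        self.Xraw = []  # raw sin/cos references, samples x 2Nh
        for R in refs.targets:
            X = R.T
            Q, _ = np.linalg.qr(X)
            self.Qx.append(Q)
            self.Xraw.append(X)
        self.A = np.stack([self.Y @ Q for Q in self.Qx])  # (N, C, 2Nh)
        self.Cyy = self.Y @ self.Y.T
        h = np.arange(1, Nh + 1)
        self.omega = 2.0 * np.pi * np.outer(grid.frequencies, h) / fs  # (N, Nh)
        self.ar_order = ar_order
        self.n_samples = n
        self.n_targets = grid.n_targets
        self._trace = float(np.trace(self.Cyy))

    def scores(self, idx):
        Cs = self.Cyy[np.ix_(idx, idx)]
        As = self.A[:, idx, :]
        gram = Cs[None] - np.einsum("nim,njm->nij", As, As)
        lam, vec = np.linalg.eigh(gram)
        Ys = self.Y[idx].T  # samples x ns
        virt, resid, counts = [], [], []
        for n in range(self.n_targets):
            ns_keep = _mec_select(lam[n])
            lam_kept = np.maximum(
                lam[n, :ns_keep], 1e-12 * max(lam[n, -1], 1e-30)
            )
            Wmat = vec[n][:, :ns_keep] / np.sqrt(lam_kept)
            Sv = Ys @ Wmat
            virt.append(Sv)
            resid.append(Sv - self.Qx[n] @ (self.Qx[n].T @ Sv))
            counts.append(ns_keep)
        a, sigma2 = burg(np.concatenate(resid, axis=1).T, self.ar_order)
        out = np.empty(self.n_targets)
        pos = 0
        zero_tol = 1e-12 * max(self._trace, 1e-30)
        for n in range(self.n_targets):
            k = counts[n]
            if lam[n, -1] <= zero_tol:
                out[n] = MEC_T_CAP
                pos += k
                continue
            om = np.broadcast_to(self.omega[n], (k, self.omega.shape[1]))
            psd = _ar_psd(a[pos : pos + k], sigma2[pos : pos + k], om)
            noise = np.maximum(self.n_samples * psd, 1e-30)  # (k, Nh)
            proj = self.Xraw[n].T @ virt[n]  # 2Nh x k
            power = (proj[0::2] ** 2 + proj[1::2] ** 2).T  # k x Nh
            out[n] = np.mean(power / noise)
            pos += k
        return out


def prepare_scorer(
    spec: MethodSpec, window: np.ndarray, fs: float, grid: StimulusGrid
) -> _Prepared:
    """Build the per-window state of ``spec`` for fast per-subset scoring."""
    window = np.atleast_2d(np.asarray(window, dtype=float))
    n_ch, n_s = window.shape
    if spec.name in {"CCA", "MSI", "FBCCA"} and n_s <= 2 * spec.Nh + n_ch:
        raise ValueError(
            f"{spec.name} needs more samples ({n_s}) than channels plus "
            f"reference dimension ({n_ch} + {2 * spec.Nh}) for full rank"
        )
    if spec.name == "CCA":
        return _PreparedCCA(window, fs, grid, spec.Nh, spec.band)
    if spec.name == "FBCCA":
        return _PreparedFBCCA(window, fs, grid, spec.Nh, spec.filterbank)
    if spec.name == "MSI":
        return _PreparedMSI(window, fs, grid, spec.Nh, spec.band)
    if spec.name == "MEC":
        if n_s <= n_ch + 2 * spec.Nh:
            raise ValueError("MEC needs samples > channels + 2*Nh")
        return _PreparedMEC(window, fs, grid, spec.Nh, spec.ar_order)
    raise ValueError(f"unknown method {spec.name!r}")


def classify_single(
    method: MethodSpec,
    window: np.ndarray,
    channel_labels: Sequence[str],
    channel_subset: Sequence[str],
    grid: StimulusGrid,
    fs: float,
) -> int:
    """Score every target on one channel subset and return the argmax index.

    Ties break to the lowest target index.  ``window`` rows are addressed by
    ``channel_labels``; unknown subset labels raise.
    """
    if len(channel_subset) == 0:
        raise ValueError("channel subset must be non-empty")
    lookup = {c.upper(): i for i, c in enumerate(channel_labels)}
    idx = []
    for lab in channel_subset:
        key = lab.upper()
        if key not in lookup:
            raise KeyError(f"channel {lab!r} not present in the window labels")
        idx.append(lookup[key])
    sub = np.asarray(window, dtype=float)[np.asarray(idx, dtype=int)]
    prep = prepare_scorer(method, sub, fs, grid)
    return prep.classify(np.arange(sub.shape[0]))
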