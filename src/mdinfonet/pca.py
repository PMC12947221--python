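"""Calpha covariance PCA: cumulative variance, projections, PC-projected
RMSF and RMSIP subspace overlap.

The model diagonalizes the covariance of the 3N-dimensional Calpha
coordinate vector of the aligned ensemble. The cumulative contribution
ratio of the top c modes is

    PCA_c = sum_{i<=c} lambda_i / sum_{i<=N} lambda_i

and the fluctuation amplitude along a mode is the RMSF of the scalar
projection series, RMSF = sqrt( (1/T) sum_t (P_t - <P>)^2 ), which on
the fitting ensemble equals sqrt(lambda) of that mode.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from mdinfonet.fluctuation import align_to_mean, pool_frames
from mdinfonet.trajio import Selection, Trajectory


@dataclass
class PCAModel:
    eigenvalues: np.ndarray     # descending, Angstrom^2
    eigenvectors: np.ndarray    # (3N, 3N), orthonormal columns
    mean: np.ndarray            # (N_sel, 3) mean structure of the fit
    sel_indices: np.ndarray     # atom indices the model was fit on

    @property
    def cumulative_ratio(self) -> np.ndarray:
        """PCA_c for c = 1..N (non-decreasing, ends at 1)."""
        return cumulative_ratio(self.eigenvalues)

    @property
    def n_modes(self) -> int:
        return self.eigenvalues.size


@dataclass
class ProjectionSeries:
    values: np.ndarray
    mode_index: int

    @property
    def mean(self) -> float:
        return float(self.values.mean())


@dataclass
class SubspaceOverlap:
    rmsip: float
    k: int


def cumulative_ratio(eigenvalues: np.ndarray) -> np.ndarray:
    lam = np.asarray(eigenvalues, dtype=float)
    total = lam.sum()
    if total <= 0:
        raise ValueError("total variance must be positive")
    return np.cumsum(lam) / total


def fit_pca(ensemble: list[Trajectory] | np.ndarray,
            sel: Selection) -> PCAModel:
    """Fit PCA on the pooled, mean-aligned Calpha coordinates.

    The ensemble is aligned to its iterated mean over ``sel``; the
    population covariance (divisor T) of the flattened (3N,) coordinate
    vectors is eigendecomposed, so the eigenvalue sum equals the total
    mean-squared fluctuation of the aligned ensemble.
    """
    frames = ensemble if isinstance(ensemble, np.ndarray) else pool_frames(ensemble)
    if frames.shape[0] < 2:
        raise ValueError("PCA requires at least 2 frames")
    aligned = align_to_mean(frames, sel)
    sub = aligned[:, sel.indices, :]
    mean = sub.mean(axis=0)
    X = (sub - mean).reshape(sub.shape[0], -1)     # (T, 3N)
    cov = X.T @ X / X.shape[0]
    lam, U = np.linalg.eigh(cov)
    order = np.argsort(lam)[::-1]
    lam = np.clip(lam[order], 0.0, None)
    U = U[:, order]
    # reproducible sign convention: largest-|component| positive
    for j in range(U.shape[1]):
        i = np.argmax(np.abs(U[:, j]))
        if U[i, j] < 0:
            U[:, j] = -U[:, j]
    return PCAModel(eigenvalues=lam, eigenvectors=U, mean=mean,
                    sel_indices=np.array(sel.indices))


def project(traj: Trajectory | np.ndarray, model: PCAModel,
            mode_index: int = 0, prealigned: bool = False) -> ProjectionSeries:
    """Project a trajectory onto one principal component.

    Frames are superposed onto the model's mean structure over the model
    selection (skip with ``prealigned=True``), mean-centered with the
    model's mean, and dotted with the chosen eigenvector per frame.
    """
    coords = traj if isinstance(traj, np.ndarray) else traj.coords
    if not (0 <= mode_index < model.n_modes):
        raise ValueError(f"mode {mode_index} out of range")
    if coords.shape[1] <= int(np.max(model.sel_indices)):
        raise ValueError(
            f"trajectory has {coords.shape[1]} atoms but the model "
            f"selection needs index {int(np.max(model.sel_indices))}")
    sub = coords[:, model.sel_indices, :]
    if sub.shape[1] != model.mean.shape[0]:
        raise ValueError("trajectory does not match the model's selection size")
    if not prealigned:
        from mdinfonet.trajio import superpose
        sel_local = Selection(np.arange(sub.shape[1]))
        sub = np.array([
            superpose(fr, model.mean, sel_local).apply(fr) for fr in sub
        ])
    X = (sub - model.mean).reshape(sub.shape[0], -1)
    vals = X @ model.eigenvectors[:, mode_index]
    return ProjectionSeries(values=vals, mode_index=mode_index)


def rmsf_along_pc(traj: Trajectory | np.ndarray, model: PCAModel,
                  mode_index: int = 0, prealigned: bool = False):
    """Fluctuation amplitude along one PC.

    Returns (scalar, per_residue) where the scalar is
    sqrt(mean_t (P_t - <P>)^2) of the projection series and the
    per-residue profile is the RMSF of the rank-1 reconstructed
    trajectory P_t * U_mode — i.e. |P_t - <P>| RMS times the per-residue
    norm of the mode vector.
    """
    ps = project(traj, model, mode_index, prealigned=prealigned)
    dev = ps.values - ps.values.mean()
    scalar = float(np.sqrt(np.mean(dev ** 2)))
    u = model.eigenvectors[:, mode_index].reshape(-1, 3)
    per_residue = scalar * np.linalg.norm(u, axis=1)
    return scalar, per_residue


def rmsip(model_a: PCAModel, model_b: PCAModel, k: int = 5) -> SubspaceOverlap:
    """Root-mean-square inner product of the two leading k-subspaces:

        RMSIP = sqrt( (1/k) sum_{i<=k} sum_{j<=k} (u_i . v_j)^2 )

    1 means identical dominant subspaces, 0 orthogonal ones. Default
    k = 5 (first five principal components).
    """
    if k > model_a.n_modes or k > model_b.n_modes:
        raise ValueError(f"k={k} exceeds available modes")
    if model_a.eigenvectors.shape[0] != model_b.eigenvectors.shape[0]:
        raise ValueError("models have different dimensions")
    A = model_a.eigenvectors[:, :k]
    B = model_b.eigenvectors[:, :k]
    val = float(np.sqrt(np.sum((A.T @ B) ** 2) / k))
    return SubspaceOverlap(rmsip=min(val, 1.0), k=k)
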