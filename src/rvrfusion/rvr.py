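"""Relevance vector regression and baseline regressors.

RVR is sparse Bayesian linear regression: each basis weight w_i carries an
independent Gaussian prior N(0, 1/alpha_i), and the precisions alpha_i plus the
noise variance sigma^2 are re-estimated by type-II maximum likelihood
(evidence maximisation).  Most alpha_i diverge during fitting, pruning their
bases; the surviving bases are the "relevance vectors".

Two basis modes are supported:

* ``kernel`` — one basis function per training sample, Phi = K = X X^T
  (linear kernel).  This is the kernel-machine convention of voxel-wise
  neuroimaging toolboxes and the right choice when voxels vastly outnumber
  subjects.
* ``primal`` — bases are the feature columns themselves, Phi = X.  Cheaper
  when only a handful of voxels survived feature selection.

The intercept is unpenalised: the training mean of y is subtracted before
fitting and added back at prediction time, so the Bayesian machinery only
models the centred response.  For a linear kernel the two modes are related
by the exact identity w = X^T mu, which ``dual_to_primal`` exploits to map a
kernel-space posterior mean back onto voxel weights for interpretation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cho_factor, cho_solve

__all__ = [
    "RVRModel",
    "PrimalWeights",
    "BaselineModel",
    "rvr_posterior",
    "rvr_fit",
    "rvr_predict",
    "dual_to_primal",
    "lr_fit",
    "lr_predict",
    "SVRAdapter",
]


@dataclass
class RVRModel:
    """Fitted relevance vector regression model.

    ``active_set`` indexes the surviving basis functions: training samples in
    kernel mode, feature columns in primal mode.  ``train_reference`` keeps
    the training rows needed to evaluate the kernel on new data (kernel mode
    only).
    """

    basis: str                      # "kernel" | "primal"
    alpha: np.ndarray               # precision of each active basis weight
    mu: np.ndarray                  # posterior mean of active weights
    sigma_posterior: np.ndarray     # posterior covariance of active weights
    noise_var: float                # sigma^2
    active_set: np.ndarray          # indices of surviving bases
    n_basis_initial: int
    y_mean: float                   # unpenalised intercept
    train_reference: np.ndarray | None = None
    converged: bool = True
    n_iter: int = 0
    n_features: int | None = None   # columns of the training X

    @property
    def is_intercept_only(self) -> bool:
        return self.mu.size == 0


@dataclass
class PrimalWeights:
    """Voxel-space weight vector (zeros at unselected voxels) plus intercept."""

    w: np.ndarray
    intercept: float
    modality_tag: str | None = None


@dataclass
class BaselineModel:
    kind: str                       # "lr" | "svr-adapter"
    w: np.ndarray | None = None
    intercept: float = 0.0
    estimator: object | None = None


def _as_2d_float(X) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError(f"expected a 2-D matrix, got shape {X.shape}")
    if not np.isfinite(X).all():
        raise ValueError("input matrix contains NaN or infinite values")
    return X


def rvr_posterior(
    Phi: np.ndarray, y: np.ndarray, alpha: np.ndarray, noise_var: float
) -> tuple[np.ndarray, np.ndarray]:
    """Posterior mean and covariance of the weights for fixed hyperparameters.

    Solves Sigma = (A + Phi^T Phi / sigma^2)^{-1}, mu = Sigma Phi^T y / sigma^2
    with A = diag(alpha).  This closed form doubles as the ridge-regression
    oracle used in the tests: for frozen alpha and sigma^2 the RVR posterior
    mean *is* a generalised ridge solution.
    """
    Phi = np.asarray(Phi, dtype=float)
    alpha = np.atleast_1d(np.asarray(alpha, dtype=float))
    H = Phi.T @ Phi / noise_var + np.diag(alpha)
    try:
        c = cho_factor(H, lower=True)
        sigma = cho_solve(c, np.eye(H.shape[0]))
    except np.linalg.LinAlgError:
        sigma = np.linalg.pinv(H)
    mu = sigma @ (Phi.T @ y) / noise_var
    return mu, sigma


def _fit_fast_sequential(
    Phi: np.ndarray,
    yc: np.ndarray,
    noise_var: float,
    tol: float,
    max_iter: int,
    update_noise: bool,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, float, bool, int]:
    """Fast marginal-likelihood maximisation (sequential add/delete/re-estimate).

    Starts from the single best-aligned basis and, per iteration, applies the
    single action (add a basis, delete one, or re-estimate its precision)
    that most increases the marginal likelihood, using the closed-form
    sparsity factors s_i = q_i^2 - ... derived from S_i and Q_i.  Much
    sparser solutions than the batch re-estimation on redundant bases.
    """
    n, m = Phi.shape
    phi_sq = np.einsum("ij,ij->j", Phi, Phi)
    phi_y = Phi.T @ yc
    y_ss = float(yc @ yc)

    # initial basis: largest normalised projection onto y
    i0 = int(np.argmax(np.where(phi_sq > 0, phi_y**2 / np.where(phi_sq > 0, phi_sq, 1), -np.inf)))
    denom0 = phi_y[i0] ** 2 / phi_sq[i0] - noise_var
    alpha = {i0: phi_sq[i0] / denom0 if denom0 > 0 else 1.0}

    mu = sigma = None
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        A = np.array(sorted(alpha))
        a_vec = np.array([alpha[i] for i in A])
        Phi_A = Phi[:, A]
        H = np.diag(a_vec) + Phi_A.T @ Phi_A / noise_var
        try:
            sigma = np.linalg.inv(H)
        except np.linalg.LinAlgError:  # pragma: no cover
            sigma = np.linalg.pinv(H)
        mu = sigma @ (phi_y[A]) / noise_var

        # S_i, Q_i for every candidate basis
        P = (Phi.T @ Phi_A) / noise_var            # m x |A|
        PS = P @ sigma
        S = phi_sq / noise_var - np.einsum("ij,ij->i", PS, P)
        Q = phi_y / noise_var - P @ (sigma @ phi_y[A]) / noise_var

        in_model = np.zeros(m, dtype=bool)
        in_model[A] = True
        a_full = np.full(m, np.inf)
        a_full[A] = a_vec
        with np.errstate(divide="ignore", invalid="ignore"):
            den = np.where(in_model, a_full - S, 1.0)
            s = np.where(in_model, a_full * S / den, S)
            q = np.where(in_model, a_full * Q / den, Q)
        theta = q**2 - s

        # likelihood change for the best action on each basis
        delta_l = np.full(m, -np.inf)
        add = (~in_model) & (theta > 0) & (S > 0)
        with np.errstate(divide="ignore", invalid="ignore"):
            delta_l[add] = 0.5 * ((Q[add] ** 2 - S[add]) / S[add]
                                  + np.log(S[add] / Q[add] ** 2))
        rees = in_model & (theta > 0)
        if rees.any():
            a_new = s[rees] ** 2 / theta[rees]
            d = 1.0 / a_new - 1.0 / a_full[rees]
            delta_l[rees] = 0.5 * (Q[rees] ** 2 * d / (S[rees] * d + 1.0)
                                   - np.log1p(S[rees] * d))
        dele = in_model & (theta <= 0)
        if len(A) > 1 and dele.any():
            delta_l[dele] = 0.5 * (Q[dele] ** 2 / (S[dele] - a_full[dele])
                                   - np.log(np.clip(1.0 - S[dele] / a_full[dele],
                                                    1e-300, None)))

        best = int(np.argmax(delta_l))
        if not np.isfinite(delta_l[best]) or delta_l[best] < tol:
            converged = True
            break

        if in_model[best] and theta[best] > 0:
            alpha[best] = float(s[best] ** 2 / theta[best])
        elif in_model[best]:
            del alpha[best]
        else:
            alpha[best] = float(s[best] ** 2 / theta[best])

        # re-estimate sigma^2 periodically; skip when the model absorbs nearly
        # all degrees of freedom (the estimate is undefined there and the
        # likelihood would collapse toward interpolation)
        if update_noise and it % 10 == 0:
            A = np.array(sorted(alpha))
            a_vec = np.array([alpha[i] for i in A])
            Phi_A = Phi[:, A]
            H = np.diag(a_vec) + Phi_A.T @ Phi_A / noise_var
            sig = np.linalg.inv(H)
            mu_t = sig @ phi_y[A] / noise_var
            rss = max(y_ss - 2 * mu_t @ phi_y[A] + mu_t @ (Phi_A.T @ Phi_A) @ mu_t, 0.0)
            dof = n - len(A) + float(np.sum(a_vec * np.diag(sig)))
            if dof > 0.05 * n:
                noise_var = max(rss / dof, 1e-12)

    A = np.array(sorted(alpha))
    a_vec = np.array([alpha[i] for i in A])
    Phi_A = Phi[:, A]
    H = np.diag(a_vec) + Phi_A.T @ Phi_A / noise_var
    sigma = np.linalg.inv(H)
    mu = sigma @ phi_y[A] / noise_var
    return A, a_vec, mu, sigma, noise_var, converged, it


def rvr_fit(
    X,
    y,
    *,
    basis: str = "kernel",
    optimizer: str = "tipping",
    alpha_init: float = 1e-4,
    noise_var_init: float | None = None,
    prune_threshold: float = 1e9,
    tol: float = 1e-6,
    max_iter: int = 1000,
    update_alpha: bool = True,
    update_noise: bool = True,
) -> RVRModel:
    """Fit relevance vector regression by Tipping's iterative re-estimation.

    The default ``optimizer="tipping"`` is the original batch re-estimation:
    gamma_i = 1 - alpha_i * Sigma_ii, alpha_i <- gamma_i / mu_i^2,
    sigma^2 <- ||y - Phi mu||^2 / (n - sum gamma); bases with
    alpha > ``prune_threshold`` are removed, and iteration stops when
    max |delta log alpha| < ``tol``.  ``optimizer="fast"`` selects the
    sequential marginal-likelihood variant (constructive add/delete/
    re-estimate), which reaches markedly sparser solutions when many bases
    are redundant.  With ``update_alpha=update_noise=False`` a single
    posterior evaluation at the initial hyperparameters is returned (the
    ridge-equivalence regime).

    A response with zero variance yields an intercept-only model that
    predicts the training mean.
    """
    X = _as_2d_float(X)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if y.size != n:
        raise ValueError(f"y has length {y.size}, expected {n}")
    if n < 3:
        raise ValueError("RVR requires at least 3 training samples")

    y_mean = float(y.mean())
    yc = y - y_mean

    if basis == "auto":
        basis = "primal" if p < n else "kernel"
    if basis not in ("kernel", "primal"):
        raise ValueError(f"unknown basis {basis!r}")

    if np.allclose(yc, 0.0):
        return RVRModel(
            basis=basis,
            alpha=np.empty(0),
            mu=np.empty(0),
            sigma_posterior=np.empty((0, 0)),
            noise_var=max(float(np.var(y)), 1e-12),
            active_set=np.empty(0, dtype=int),
            n_basis_initial=n if basis == "kernel" else p,
            y_mean=y_mean,
            train_reference=X if basis == "kernel" else None,
            n_features=p,
        )

    Phi_full = X @ X.T if basis == "kernel" else X
    m = Phi_full.shape[1]

    if optimizer == "fast":
        nv0 = (
            float(noise_var_init)
            if noise_var_init is not None
            else max(0.1 * float(np.var(yc)), 1e-6)
        )
        active, alpha, mu, sigma, noise_var, converged, n_iter = _fit_fast_sequential(
            Phi_full, yc, nv0, tol, max_iter, update_noise
        )
        if not converged:
            warnings.warn(
                f"fast RVR did not converge in {max_iter} iterations",
                RuntimeWarning,
            )
        return RVRModel(
            basis=basis,
            alpha=np.atleast_1d(alpha),
            mu=np.atleast_1d(mu),
            sigma_posterior=np.atleast_2d(sigma),
            noise_var=noise_var,
            active_set=np.asarray(active, dtype=int),
            n_basis_initial=m,
            y_mean=y_mean,
            train_reference=X if basis == "kernel" else None,
            converged=converged,
            n_iter=n_iter,
            n_features=p,
        )
    if optimizer != "tipping":
        raise ValueError(f"unknown optimizer {optimizer!r}")

    active = np.arange(m)
    alpha = np.full(m, alpha_init, dtype=float)
    noise_var = (
        float(noise_var_init)
        if noise_var_init is not None
        else max(0.1 * float(np.var(yc)), 1e-6)
    )

    # Gram matrix and projections are fixed across iterations; each posterior
    # solve only touches the active submatrix
    G = Phi_full.T @ Phi_full
    b = Phi_full.T @ yc
    y_ss = float(yc @ yc)

    def _solve(idx, alph, s2):
        H = G[np.ix_(idx, idx)] / s2 + np.diag(alph)
        try:
            sig = np.linalg.inv(H)
        except np.linalg.LinAlgError:  # pragma: no cover
            sig = np.linalg.pinv(H)
        return sig @ b[idx] / s2, sig

    mu, sigma = _solve(active, alpha, noise_var)
    converged = not (update_alpha or update_noise)
    n_iter = 0

    if update_alpha or update_noise:
        for n_iter in range(1, max_iter + 1):
            gamma = np.clip(1.0 - alpha * np.diag(sigma), 1e-12, None)

            if update_alpha:
                with np.errstate(divide="ignore"):
                    alpha_new = gamma / np.where(mu**2 > 0, mu**2, np.inf)
                alpha_new = np.where(np.isfinite(alpha_new), alpha_new, 2 * prune_threshold)
            else:
                alpha_new = alpha

            # sigma^2 <- rss / (n - sum gamma) is undefined when the model
            # absorbs nearly all degrees of freedom (sum gamma ~ n, the
            # interpolation regime); skip the update until pruning frees dof
            if update_noise and float(gamma.sum()) <= 0.95 * len(yc):
                # ||y - Phi mu||^2 without forming the n-vector
                Ga = G[np.ix_(active, active)]
                rss = max(y_ss - 2.0 * float(mu @ b[active]) + float(mu @ Ga @ mu), 0.0)
                denom = len(yc) - float(gamma.sum())
                noise_var = max(rss / denom, 1e-12)

            keep = alpha_new <= prune_threshold
            if not keep.any():
                # everything pruned: fall back to intercept-only behaviour
                active = np.empty(0, dtype=int)
                alpha = mu = np.empty(0)
                sigma = np.empty((0, 0))
                converged = True
                break

            delta = np.abs(np.log(alpha_new[keep]) - np.log(alpha[keep])).max()
            alpha = alpha_new[keep]
            active = active[keep]
            mu, sigma = _solve(active, alpha, noise_var)

            if delta < tol:
                converged = True
                break
        else:
            converged = False
            warnings.warn(
                f"RVR did not converge in {max_iter} iterations "
                f"(last max |delta log alpha| step above tol={tol})",
                RuntimeWarning,
            )

    return RVRModel(
        basis=basis,
        alpha=np.atleast_1d(alpha),
        mu=np.atleast_1d(mu),
        sigma_posterior=np.atleast_2d(sigma),
        noise_var=noise_var,
        active_set=active,
        n_basis_initial=m,
        y_mean=y_mean,
        train_reference=X if basis == "kernel" else None,
        converged=converged,
        n_iter=n_iter,
        n_features=p,
    )


def rvr_predict(model: RVRModel, X_test) -> np.ndarray:
    """Point predictions Phi(X_test) mu + intercept."""
    X_test = _as_2d_float(X_test)
    if model.n_features is not None and X_test.shape[1] != model.n_features:
        raise ValueError(
            f"X_test has {X_test.shape[1]} columns, model was trained on "
            f"{model.n_features}"
        )
    if model.is_intercept_only:
        return np.full(X_test.shape[0], model.y_mean)
    if model.basis == "kernel":
        K = X_test @ model.train_reference[model.active_set].T
        return K @ model.mu + model.y_mean
    return X_test[:, model.active_set] @ model.mu + model.y_mean


def dual_to_primal(
    model: RVRModel,
    *,
    selected_indices: np.ndarray | None = None,
    n_total_voxels: int | None = None,
    modality_tag: str | None = None,
) -> PrimalWeights:
    """Back-project a fitted model onto voxel-space weights.

    Kernel mode uses the linear-kernel identity w = X_train^T mu over the
    active samples; primal mode re-embeds mu at the active feature columns.
    ``selected_indices``/``n_total_voxels`` re-embed the weights of the
    selected-feature subspace into the full per-modality voxel space, with
    zeros at unselected voxels.
    """
    if model.is_intercept_only:
        w_sel = np.zeros(model.n_features or 0)
    elif model.basis == "kernel":
        w_sel = model.train_reference[model.active_set].T @ model.mu
    elif model.basis == "primal":
        w_sel = np.zeros(model.n_features)
        w_sel[model.active_set] = model.mu
    else:  # pragma: no cover
        raise ValueError(f"unsupported basis {model.basis!r} for back-projection")

    if selected_indices is None:
        w_full = w_sel
    else:
        selected_indices = np.asarray(selected_indices, dtype=int)
        if n_total_voxels is None:
            raise ValueError("n_total_voxels is required with selected_indices")
        if len(selected_indices) != len(w_sel):
            raise ValueError("selected_indices length does not match weight count")
        w_full = np.zeros(n_total_voxels)
        w_full[selected_indices] = w_sel
    return PrimalWeights(w=w_full, intercept=model.y_mean, modality_tag=modality_tag)


def lr_fit(X, y) -> BaselineModel:
    """Minimum-norm least squares with an unpenalised intercept.

    Centred pseudo-inverse solution: exact on training data whenever the
    centred system is consistent (always in the under-determined case), with
    the smallest-norm weight vector among exact solutions.
    """
    X = _as_2d_float(X)
    y = np.asarray(y, dtype=float).ravel()
    if X.shape[0] != y.size:
        raise ValueError("X and y row counts differ")
    if X.shape[0] < 2:
        raise ValueError("linear regression requires at least 2 samples")
    x_mean = X.mean(axis=0)
    y_mean = float(y.mean())
    w = np.linalg.pinv(X - x_mean) @ (y - y_mean)
    return BaselineModel(kind="lr", w=w, intercept=y_mean - float(x_mean @ w))


def lr_predict(model: BaselineModel, X_test) -> np.ndarray:
    X_test = _as_2d_float(X_test)
    if model.kind == "svr-adapter":
        return np.asarray(model.estimator.predict(X_test), dtype=float)
    return X_test @ model.w + model.intercept


class SVRAdapter:
    """Thin adapter around any scikit-learn style SVR estimator.

    The comparison experiment only needs ``fit``/``predict``; internals of the
    support vector machine are deliberately out of scope.  By default wraps
    ``sklearn.svm.SVR(kernel="linear")``.
    """

    def __init__(self, estimator=None):
        if estimator is None:
            from sklearn.svm import SVR

            estimator = SVR(kernel="linear")
        self.estimator = estimator

    def fit(self, X, y) -> BaselineModel:
        import copy

        est = copy.deepcopy(self.estimator)
        est.fit(_as_2d_float(X), np.asarray(y, dtype=float).ravel())
        return BaselineModel(kind="svr-adapter", estimator=est)
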