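"""Maximum-likelihood mixture of ICA models with adaptive source densities.

A mixture of ``M`` complete ICA models competes for the data: model ``h``
has an unmixing matrix ``W_h``, a bias ``c_h`` and one generalized-Gaussian
density per source,

    log q(s) = log(rho / (2 * beta * Gamma(1/rho))) - |s / beta|**rho,

whose shape ``rho`` and scale ``beta`` are adapted during fitting.  Each
sample's posterior responsibility over models is computed from the
per-sample model log-likelihoods and the mixture priors; unmixing matrices
are updated by responsibility-weighted natural-gradient steps, density
scales in closed form, shapes by a bounded line search, and priors as mean
responsibilities.  The learning rate anneals: any step that decreases the
total log-likelihood is reverted and the rate halved.

The estimator follows scikit-learn conventions (``fit(X)`` with samples in
rows, fitted attributes with trailing underscores) and whitens/reduces the
data with PCA before fitting, mirroring common practice for high-density
EEG decompositions.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln, logsumexp
from scipy import stats
from sklearn.base import BaseEstimator
from sklearn.decomposition import PCA
from sklearn.utils.validation import check_is_fitted

__all__ = ["ICAModel", "MixtureICA", "amari_index", "anova_model_probabilities",
           "classify_trials_by_model", "save_mixture", "load_mixture"]

_RHO_BOUNDS = (0.5, 4.0)
_ABS_FLOOR = 1e-8  # |s| floor: the score diverges at s=0 when rho < 1


@dataclass
class ICAModel:
    """One complete ICA model of the mixture."""

    W: np.ndarray          # (n, n) unmixing matrix in whitened space
    c: np.ndarray          # (n,) bias
    rho: np.ndarray        # (n,) generalized-Gaussian shapes
    beta: np.ndarray       # (n,) generalized-Gaussian scales

    def copy(self) -> "ICAModel":
        return ICAModel(self.W.copy(), self.c.copy(), self.rho.copy(), self.beta.copy())


def _gg_logconst(rho: np.ndarray, beta: np.ndarray) -> np.ndarray:
    return np.log(rho) - np.log(2 * beta) - gammaln(1.0 / rho)


def _model_loglik(model: ICAModel, Z: np.ndarray):
    """Per-sample log-likelihood of one ICA model; returns (loglik, sources)."""
    S = model.W @ (Z - model.c[:, None])
    a = np.maximum(np.abs(S) / model.beta[:, None], _ABS_FLOOR)
    logdet = np.linalg.slogdet(model.W)[1]
    ll = logdet + np.sum(_gg_logconst(model.rho, model.beta)) \
        - np.einsum("it->t", a ** model.rho[:, None])
    return ll, S


class MixtureICA(BaseEstimator):
    """Mixture of complete ICA models fitted by annealed natural gradient.

    Parameters
    ----------
    n_models : number of competing ICA models (2 captures a two-regime
        hypothesis such as distinct knee vs ankle source distributions).
    n_components : PCA dimensionality the data are whitened and reduced to
        before fitting; ``None`` keeps all channels.
    max_iter, tol : stopping rule; ``tol`` is the absolute per-sample
        log-likelihood change below which fitting stops.
    lrate : initial natural-gradient learning rate.
    rho_update_interval : iterations between shape-parameter line searches.
    refine_iter : extra classification-EM iterations run after the soft fit
        with hard (argmax) responsibilities.  Once the soft mixture has
        specialised, hard assignment removes the residual cross-regime
        leakage through fractional responsibilities and sharpens each
        model's unmixing matrix; set 0 to disable.
    random_state : seed for the orthogonal initialisation of each model.

    Attributes
    ----------
    models_ : list of fitted :class:`ICAModel` (in whitened space).
    priors_ : (n_models,) mixture weights.
    loglik_trace_ : per-iteration total log-likelihood (accepted steps).
    pca_ : fitted PCA/whitening transform (``None`` if whiten=False).
    """

    def __init__(self, n_models: int = 2, n_components: int | None = None,
                 max_iter: int = 200, tol: float = 1e-6, lrate: float = 0.2,
                 rho_update_interval: int = 5, whiten: bool = True,
                 refine_iter: int = 200, random_state: int | None = None):
        self.n_models = n_models
        self.n_components = n_components
        self.max_iter = max_iter
        self.tol = tol
        self.lrate = lrate
        self.rho_update_interval = rho_update_interval
        self.whiten = whiten
        self.refine_iter = refine_iter
        self.random_state = random_state

    # -- fitting ----------------------------------------------------------

    def _fit_whitener(self, X: np.ndarray) -> np.ndarray:
        if self.whiten:
            n_comp = self.n_components or X.shape[1]
            self.pca_ = PCA(n_components=n_comp, whiten=True,
                            svd_solver="covariance_eigh", random_state=0)
            Z = self.pca_.fit_transform(X).T
        else:
            if self.n_components not in (None, X.shape[1]):
                raise ValueError("n_components requires whiten=True")
            self.pca_ = None
            self.mean_ = X.mean(axis=0)
            Z = (X - self.mean_).T
        return np.ascontiguousarray(Z)

    def fit(self, X: np.ndarray, y=None) -> "MixtureICA":
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2-D (n_samples, n_channels)")
        Z = self._fit_whitener(X)
        n, T = Z.shape
        if T < 20 * n * n:
            raise ValueError(f"need at least {20 * n * n} samples for {n} components")
        rng = np.random.default_rng(self.random_state)

        models = []
        for _ in range(self.n_models):
            Q = stats.ortho_group.rvs(n, random_state=rng) if n > 1 else np.ones((1, 1))
            models.append(ICAModel(W=Q, c=np.zeros(n),
                                   rho=np.full(n, 1.5), beta=np.ones(n)))
        priors = np.full(self.n_models, 1.0 / self.n_models)

        lrate = float(self.lrate)
        trace: list[float] = []
        prev_ll = -np.inf
        prev_state = None
        failures = 0
        just_reverted = False
        eye = np.eye(n)

        for it in range(self.max_iter):
            per_model = [_model_loglik(m, Z) for m in models]
            L = np.stack([ll for ll, _ in per_model])          # (M, T)
            R = L + np.log(priors)[:, None]
            norm = logsumexp(R, axis=0)
            total = float(norm.sum())

            if not np.isfinite(total) or total < prev_ll - 1e-8 * T:
                # reject: revert to the previous accepted state, anneal
                if prev_state is None:
                    raise RuntimeError("mixture ICA diverged at initialisation")
                models = [m.copy() for m in prev_state[0]]
                priors = prev_state[1].copy()
                lrate *= 0.5
                just_reverted = True
                failures += 1
                if failures >= 10:
                    raise RuntimeError(
                        f"mixture ICA failed to make progress after {failures} "
                        f"consecutive rejected steps (lrate={lrate:.2e}, "
                        f"last loglik={prev_ll:.6g})")
                continue

            failures = 0
            trace.append(total)
            converged = (np.isfinite(prev_ll) and not just_reverted
                         and abs(total - prev_ll) < self.tol * T)
            just_reverted = False
            prev_ll = total
            prev_state = ([m.copy() for m in models], priors.copy())
            if converged:
                break
            lrate = min(lrate * 1.05, 0.5)

            gamma = np.exp(R - norm)                           # (M, T)
            N_h = gamma.sum(axis=1) + 1e-300
            priors = N_h / T
            do_rho = (it % self.rho_update_interval) == self.rho_update_interval - 1
            for h, m in enumerate(models):
                _, S = per_model[h]
                g = gamma[h]
                a = np.maximum(np.abs(S), _ABS_FLOOR)
                phi = (m.rho[:, None] / m.beta[:, None]
                       * np.sign(S) * (a / m.beta[:, None]) ** (m.rho[:, None] - 1))
                Mmat = ((phi * g) @ S.T) / N_h[h]
                m.W = m.W + lrate * (eye - Mmat) @ m.W
                # bias: responsibility-weighted data mean
                m.c = (Z @ g) / N_h[h]
                if do_rho:
                    m.rho = _update_shapes(S, g, N_h[h], m.rho)
                # closed-form ML scale for the (possibly new) shape:
                # beta^rho = rho * E[|s|^rho]
                mom = ((a ** m.rho[:, None]) * g).sum(axis=1) / N_h[h]
                m.beta = (m.rho * mom) ** (1.0 / m.rho)

        if self.refine_iter > 0 and self.n_models > 1:
            models, priors = self._refine_hard(Z, models, priors)

        self.models_ = models
        self.priors_ = priors
        self.loglik_trace_ = np.asarray(trace)
        self.n_iter_ = len(trace)
        self.n_features_in_ = X.shape[1]
        return self

    def _refine_hard(self, Z, models, priors):
        """Classification-EM refinement.

        Samples are hard-assigned to their argmax-responsibility model
        once, and each model is then polished on its own samples with the
        single-model annealed natural-gradient loop.  With a specialised
        mixture the hard partition is essentially pure, so this removes
        the cross-regime leakage that fractional responsibilities leave in
        the unmixing matrices.  Each model is refitted both from its
        current state and from a fresh random rotation — the soft phase
        can leave one model in a poor basin even when the partition is
        already correct — and the better final likelihood wins.
        """
        n, T = Z.shape
        rng = np.random.default_rng(self.random_state)
        L = np.stack([_model_loglik(m, Z)[0] for m in models])
        assign = np.argmax(L + np.log(priors)[:, None], axis=0)
        counts = np.bincount(assign, minlength=self.n_models)
        for h, m in enumerate(models):
            if counts[h] < 20 * n:
                continue
            Zh = np.ascontiguousarray(Z[:, assign == h])
            # the subset is not white under the pooled whitening, which can
            # slow the natural gradient badly for ill-conditioned regime
            # mixings; re-whiten locally and fit in that frame
            mu = Zh.mean(axis=1)
            Zc = Zh - mu[:, None]
            evals, evecs = np.linalg.eigh((Zc @ Zc.T) / Zh.shape[1])
            evals = np.maximum(evals, 1e-12 * evals.max())
            Wl = (evecs / np.sqrt(evals)) @ evecs.T          # symmetric whitener
            Zw = np.ascontiguousarray(Wl @ Zc)
            Wl_inv = evecs * np.sqrt(evals) @ evecs.T
            cont = m.copy()
            cont.W = m.W @ Wl_inv
            cont.c = Wl @ (m.c - mu)
            candidates = [cont]
            if n > 1:
                candidates.append(ICAModel(
                    W=stats.ortho_group.rvs(n, random_state=rng),
                    c=np.zeros(n), rho=np.full(n, 1.5), beta=np.ones(n)))
            best = None
            for cand in candidates:
                _fit_one_model(Zw, cand, max_iter=self.refine_iter, tol=self.tol,
                               lrate0=self.lrate,
                               rho_interval=self.rho_update_interval)
                ll = float(_model_loglik(cand, Zw)[0].sum())
                if best is None or ll > best[0]:
                    best = (ll, cand)
            win = best[1]
            # map back to the pooled-whitened frame:
            # s = W_w (Wl (z - mu) - c_w) = (W_w Wl)(z - (mu + Wl^-1 c_w))
            models[h] = ICAModel(W=win.W @ Wl, c=mu + Wl_inv @ win.c,
                                 rho=win.rho, beta=win.beta)
        priors = (counts + 1e-300) / T
        return models, priors

    # -- inference --------------------------------------------------------

    def _reduce(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if self.pca_ is not None:
            return self.pca_.transform(X).T
        return (X - self.mean_).T

    def score_models(self, X: np.ndarray) -> np.ndarray:
        """Per-sample log-likelihood of each model: (n_models, n_samples)."""
        check_is_fitted(self, "models_")
        Z = self._reduce(X)
        return np.stack([_model_loglik(m, Z)[0] for m in self.models_])

    def responsibilities(self, X: np.ndarray) -> np.ndarray:
        """Per-sample posterior model probabilities: (n_models, n_samples)."""
        R = self.score_models(X) + np.log(self.priors_)[:, None]
        return np.exp(R - logsumexp(R, axis=0))

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Most probable model per sample."""
        return np.argmax(self.responsibilities(X), axis=0)

    def model_probability(self, X_segment: np.ndarray) -> np.ndarray:
        """Posterior probability that each model generated a whole segment.

        ``p_h = softmax_h(log pi_h + sum_t L_h(x_t))``, evaluated in the log
        domain with max subtraction.
        """
        L = self.score_models(X_segment).sum(axis=1) + np.log(self.priors_)
        L -= L.max()
        p = np.exp(L)
        return p / p.sum()

    def transform(self, X: np.ndarray, model: int = 0) -> np.ndarray:
        """Source activations of one model: (n_samples, n_components)."""
        check_is_fitted(self, "models_")
        m = self.models_[model]
        Z = self._reduce(X)
        return (m.W @ (Z - m.c[:, None])).T

    def unmixing(self, model: int = 0) -> np.ndarray:
        """Unmixing matrix in whitened/reduced space."""
        check_is_fitted(self, "models_")
        return self.models_[model].W

    def scalp_maps(self, model: int = 0) -> np.ndarray:
        """Mixing columns mapped back to channel space: (n_channels, n_comp).

        Column ``i`` is the scalp projection pattern of source ``i``.
        """
        check_is_fitted(self, "models_")
        A = np.linalg.inv(self.models_[model].W)       # whitened-space mixing
        if self.pca_ is None:
            return A
        scale = np.sqrt(self.pca_.explained_variance_)
        return self.pca_.components_.T @ (A * scale[:, None])


def save_mixture(mixica: MixtureICA, stem) -> None:
    """Persist a fitted mixture as ``<stem>.json`` + ``<stem>.bin``.

    The ``.bin`` file holds all arrays concatenated as little-endian
    float64 (``<f8``); the JSON carries, per array, its name, byte offset
    and shape (C order), plus the estimator parameters.  The format is
    self-describing and platform-independent.
    """
    import json
    from pathlib import Path

    check_is_fitted(mixica, "models_")
    stem = Path(stem)
    arrays: list[tuple[str, np.ndarray]] = [("priors", np.asarray(mixica.priors_))]
    for h, m in enumerate(mixica.models_):
        for field_name in ("W", "c", "rho", "beta"):
            arrays.append((f"model{h}/{field_name}", getattr(m, field_name)))
    if mixica.pca_ is not None:
        arrays += [("pca/components", mixica.pca_.components_),
                   ("pca/explained_variance", mixica.pca_.explained_variance_),
                   ("pca/mean", mixica.pca_.mean_)]
    else:
        arrays.append(("mean", mixica.mean_))
    index = []
    offset = 0
    with open(stem.with_suffix(".bin"), "wb") as fh:
        for name, arr in arrays:
            data = np.ascontiguousarray(arr, dtype="<f8")
            fh.write(data.tobytes())
            index.append({"name": name, "offset": offset, "shape": list(data.shape)})
            offset += data.nbytes
    meta = {"format": "erdica-mixture-v1", "dtype": "<f8", "arrays": index,
            "params": {k: v for k, v in mixica.get_params().items()}}
    stem.with_suffix(".json").write_text(json.dumps(meta, indent=1))


def load_mixture(stem) -> MixtureICA:
    """Load a mixture saved by :func:`save_mixture`."""
    import json
    from pathlib import Path
    from sklearn.decomposition import PCA

    stem = Path(stem)
    meta = json.loads(stem.with_suffix(".json").read_text())
    if meta.get("format") != "erdica-mixture-v1":
        raise ValueError("unrecognised mixture file format")
    raw = stem.with_suffix(".bin").read_bytes()
    arrays = {}
    for entry in meta["arrays"]:
        shape = tuple(entry["shape"])
        count = int(np.prod(shape)) if shape else 1
        arr = np.frombuffer(raw, dtype="<f8", count=count,
                            offset=entry["offset"]).reshape(shape)
        arrays[entry["name"]] = arr.astype(float)
    mix = MixtureICA(**meta["params"])
    mix.priors_ = arrays["priors"]
    mix.models_ = []
    for h in range(mix.n_models):
        mix.models_.append(ICAModel(W=arrays[f"model{h}/W"], c=arrays[f"model{h}/c"],
                                    rho=arrays[f"model{h}/rho"],
                                    beta=arrays[f"model{h}/beta"]))
    if "pca/components" in arrays:
        pca = PCA(n_components=arrays["pca/components"].shape[0], whiten=True)
        pca.components_ = arrays["pca/components"]
        pca.explained_variance_ = arrays["pca/explained_variance"]
        pca.mean_ = arrays["pca/mean"]
        mix.pca_ = pca
    else:
        mix.pca_ = None
        mix.mean_ = arrays["mean"]
    mix.n_features_in_ = (mix.pca_.components_.shape[1] if mix.pca_ is not None
                          else mix.mean_.shape[0])
    return mix


def _fit_one_model(Z: np.ndarray, model: ICAModel, max_iter: int, tol: float,
                   lrate0: float, rho_interval: int) -> None:
    """Annealed natural-gradient fit of a single ICA model, in place."""
    n, T = Z.shape
    eye = np.eye(n)
    lrate = float(lrate0)
    prev_ll = -np.inf
    prev_state = None
    just_reverted = False
    for it in range(max_iter):
        ll_t, S = _model_loglik(model, Z)
        total = float(ll_t.sum())
        if not np.isfinite(total) or total < prev_ll - 1e-8 * T:
            if prev_state is None:
                break
            model.W, model.c, model.rho, model.beta = (x.copy() for x in prev_state)
            lrate *= 0.5
            just_reverted = True
            if lrate < 1e-5:
                break
            continue
        if (np.isfinite(prev_ll) and not just_reverted
                and abs(total - prev_ll) < tol * T):
            break
        just_reverted = False
        prev_ll = total
        prev_state = (model.W.copy(), model.c.copy(), model.rho.copy(),
                      model.beta.copy())
        lrate = min(lrate * 1.05, 0.5)
        a = np.maximum(np.abs(S), _ABS_FLOOR)
        phi = (model.rho[:, None] / model.beta[:, None]
               * np.sign(S) * (a / model.beta[:, None]) ** (model.rho[:, None] - 1))
        Mmat = (phi @ S.T) / T
        model.W = model.W + lrate * (eye - Mmat) @ model.W
        model.c = Z.mean(axis=1)
        if (it % rho_interval) == rho_interval - 1:
            model.rho = _update_shapes(S, np.ones(T), float(T), model.rho)
        mom = (a ** model.rho[:, None]).mean(axis=1)
        model.beta = (model.rho * mom) ** (1.0 / model.rho)


def _update_shapes(S: np.ndarray, g: np.ndarray, N: float, rho: np.ndarray,
                   n_golden: int = 14) -> np.ndarray:
    """Golden-section profile-likelihood update of each source's shape.

    For a candidate shape the optimal scale is closed-form, so the profiled
    per-source objective is
        f(rho) = log(rho) - log(2*beta*) - lgamma(1/rho) - 1/rho
    with beta*^rho = rho * m(rho), m(rho) = E_g[|s|^rho].
    """
    # stride-subsample long recordings: the shape estimate needs far fewer
    # samples than the unmixing matrix does
    T = S.shape[1]
    stride = max(T // 20000, 1)
    a = np.maximum(np.abs(S[:, ::stride]), _ABS_FLOOR)
    g_s = g[::stride]
    N_s = g_s.sum() + 1e-300
    log_a = np.log(a)

    def objective(r: np.ndarray) -> np.ndarray:
        mom = (np.exp(r[:, None] * log_a) * g_s).sum(axis=1) / N_s
        beta = (r * mom) ** (1.0 / r)
        return np.log(r) - np.log(2 * beta) - gammaln(1.0 / r) - 1.0 / r

    lo = np.full_like(rho, _RHO_BOUNDS[0])
    hi = np.full_like(rho, _RHO_BOUNDS[1])
    invphi = (np.sqrt(5.0) - 1) / 2
    for _ in range(n_golden):
        x1 = hi - invphi * (hi - lo)
        x2 = lo + invphi * (hi - lo)
        left = objective(x1) >= objective(x2)
        hi = np.where(left, x2, hi)
        lo = np.where(left, lo, x1)
    return (lo + hi) / 2


# --- utilities ------------------------------------------------------------

def amari_index(W_est: np.ndarray, A_true: np.ndarray) -> float:
    """Permutation- and scale-invariant ICA recovery error in [0, 1].

    Zero iff ``W_est @ A_true`` is a permutation of a diagonal matrix.
    """
    P = np.abs(np.asarray(W_est) @ np.asarray(A_true))
    n = P.shape[0]
    if P.shape != (n, n):
        raise ValueError("W_est @ A_true must be square")
    row = (P.sum(axis=1) / P.max(axis=1) - 1).sum()
    col = (P.sum(axis=0) / P.max(axis=0) - 1).sum()
    return float((row + col) / (2 * n * (n - 1)))


def anova_model_probabilities(groups) -> tuple[float, float]:
    """One-way fixed-effects ANOVA across groups of model probabilities.

    ``groups`` is a sequence of 1-D arrays (e.g. per-subject model-1
    probabilities for the knee-trial subset and the ankle-trial subset).
    Returns ``(F, p)``.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    with np.errstate(invalid="ignore", divide="ignore"):
        F, p = stats.f_oneway(*groups)
    if np.isnan(F):    # zero variance everywhere: identical groups -> F=0
        means = [g.mean() for g in groups]
        if np.ptp(means) == 0:
            return 0.0, 1.0
        return float("inf"), 0.0
    return float(F), float(p)


def classify_trials_by_model(mixica: MixtureICA, eeg: np.ndarray, fs: float,
                             events) -> dict:
    """Assign each trial to the mixture model that best fits it.

    For every trial the posterior model probability is computed over
    ``[onset, offset)`` and the argmax model taken.  The model-to-label
    mapping (which model means "knee", which "ankle") is chosen as the one
    of the ``M!`` permutations that maximises agreement with the joint
    factor over all trials.  Returns overall plus per-mode accuracies, the
    chosen mapping, and per-trial labels.

    ``eeg`` is (n_channels, n_samples); ``events`` a DataFrame with
    ``onset_sample``, ``offset_sample``, ``joint`` and ``mode`` columns.
    """
    check_is_fitted(mixica, "models_")
    joints = sorted(events["joint"].unique())
    if len(joints) > mixica.n_models:
        raise ValueError("more joint categories than mixture models")
    pred_model = np.empty(len(events), dtype=int)
    probs = np.empty((len(events), mixica.n_models))
    for i, ev in enumerate(events.itertuples(index=False)):
        seg = eeg[:, int(ev.onset_sample):int(ev.offset_sample)].T
        p = mixica.model_probability(seg)
        probs[i] = p
        pred_model[i] = int(np.argmax(p))
    true = events["joint"].to_numpy()

    best_map, best_acc = None, -1.0
    for perm in itertools.permutations(range(mixica.n_models), len(joints)):
        mapping = {model: joint for model, joint in zip(perm, joints)}
        pred = np.array([mapping.get(m, "unassigned") for m in pred_model])
        acc = float(np.mean(pred == true))
        if acc > best_acc:
            best_acc, best_map = acc, mapping
    pred_joint = np.array([best_map.get(m, "unassigned") for m in pred_model])
    out = {
        "accuracy": best_acc,
        "mapping": best_map,
        "per_trial_model": pred_model,
        "per_trial_joint": pred_joint,
        "model_probabilities": probs,
    }
    for mode in sorted(events["mode"].unique()):
        sel = (events["mode"] == mode).to_numpy()
        out[f"accuracy_{mode}"] = float(np.mean(pred_joint[sel] == true[sel]))
    return out
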