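"""Latent class analysis for polytomous indicators.

The model is a finite mixture of products of multinomials: with class
prevalences pi_c and item-response probabilities rho_{jck},

    P(Y_i) = sum_c pi_c prod_j rho_{j, c, y_ij},

fitted by EM from random Dirichlet(1) starts with multiple restarts.
Observations are aggregated into distinct response patterns before fitting,
so each EM iteration costs O(#patterns * K * J) regardless of cohort size
(with five indicators there are at most 288 patterns).

Model selection follows the registry-analysis convention: minimize BIC (AIC
below 500 observations), require normalized entropy >= 0.8, average posterior
per assigned class >= 0.5, smallest modal class > 5%, and optionally a
parametric bootstrap likelihood-ratio test of K vs K-1 classes.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .cohort import Cohort, indicator_codes

__all__ = [
    "LCAParameters",
    "PosteriorMatrix",
    "ClassAssignment",
    "FitDiagnostics",
    "ModelScan",
    "SelectionRules",
    "UNASSIGNED",
    "em_fit",
    "log_likelihood",
    "posterior",
    "assign_classes",
    "diagnostics",
    "bootstrap_lrt",
    "scan_models",
    "reorder_classes",
    "project_classes",
    "sample_from_parameters",
    "parameters_from_distributions",
]

#: Label used for patients whose maximum posterior falls below the cutoff.
#: Class labels themselves are 1-based (class 1 .. class K).
UNASSIGNED = 0

_RHO_FLOOR = 1e-12  # floor applied inside logs only; reported rho is unfloored


@dataclass
class LCAParameters:
    """Fitted (or constructed) mixture parameters.

    ``item_response[name]`` has shape ``(K, m_j)`` with rows summing to 1 in
    the category order of ``levels[name]``.
    """

    levels: dict[str, list[str]]
    class_prevalence: np.ndarray
    item_response: dict[str, np.ndarray]
    log_likelihood: float
    n_obs: int
    converged: bool = True
    n_iterations: int = 0
    restart_loglik: tuple[float, ...] = ()
    loglik_trace: tuple[float, ...] = ()
    degenerate_indicators: tuple[str, ...] = ()

    @property
    def n_classes(self) -> int:
        return len(self.class_prevalence)

    @property
    def n_free_params(self) -> int:
        """(K-1) + K * sum_j (m_j - 1), counting observed categories only."""
        K = self.n_classes
        per_item = 0
        for name, rho in self.item_response.items():
            m_obs = len(self.levels[name])
            if name in self.degenerate_indicators:
                m_obs = 1
            per_item += m_obs - 1
        return (K - 1) + K * per_item

    def to_dict(self) -> dict:
        return {
            "levels": {k: list(v) for k, v in self.levels.items()},
            "class_prevalence": self.class_prevalence.tolist(),
            "item_response": {k: v.tolist() for k, v in self.item_response.items()},
            "log_likelihood": float(self.log_likelihood),
            "n_obs": int(self.n_obs),
            "converged": bool(self.converged),
            "n_iterations": int(self.n_iterations),
            "n_free_params": int(self.n_free_params),
            "degenerate_indicators": list(self.degenerate_indicators),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "LCAParameters":
        return cls(
            levels={k: list(v) for k, v in d["levels"].items()},
            class_prevalence=np.asarray(d["class_prevalence"], dtype=float),
            item_response={
                k: np.asarray(v, dtype=float) for k, v in d["item_response"].items()
            },
            log_likelihood=float(d["log_likelihood"]),
            n_obs=int(d["n_obs"]),
            converged=bool(d.get("converged", True)),
            n_iterations=int(d.get("n_iterations", 0)),
            degenerate_indicators=tuple(d.get("degenerate_indicators", ())),
        )


@dataclass
class PosteriorMatrix:
    """Per-patient class-membership probabilities theta (n x K, rows sum to 1)."""

    theta: np.ndarray
    patient_id: np.ndarray

    @property
    def n(self) -> int:
        return self.theta.shape[0]

    @property
    def n_classes(self) -> int:
        return self.theta.shape[1]

    def permute(self, order: np.ndarray) -> "PosteriorMatrix":
        return PosteriorMatrix(self.theta[:, order], self.patient_id)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.theta, columns=[f"class_{c + 1}" for c in range(self.n_classes)]
        )
        df.insert(0, "patient_id", self.patient_id)
        return df


@dataclass
class ClassAssignment:
    """Modal class labels (1-based; 0 = unassigned) under a posterior cutoff."""

    labels: np.ndarray
    max_posterior: np.ndarray
    cutoff: float
    patient_id: np.ndarray
    n_ties: int = 0

    @property
    def unassigned_fraction(self) -> float:
        return float(np.mean(self.labels == UNASSIGNED))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "patient_id": self.patient_id,
                "class_label": self.labels,
                "max_posterior": self.max_posterior,
            }
        )


@dataclass
class FitDiagnostics:
    """Information criteria and classification-quality summaries for one fit."""

    n_classes: int
    log_likelihood: float
    n_free_params: int
    n_obs: int
    aic: float
    bic: float
    sabic: float
    entropy_raw: float
    entropy_normalized: float
    min_class_share: float
    mean_posterior_per_class: np.ndarray
    boot_lrt_p: float | None = None

    def to_dict(self) -> dict:
        d = {
            "n_classes": self.n_classes,
            "log_likelihood": float(self.log_likelihood),
            "n_free_params": self.n_free_params,
            "aic": float(self.aic),
            "bic": float(self.bic),
            "sabic": float(self.sabic),
            "entropy_raw": float(self.entropy_raw),
            "entropy_normalized": float(self.entropy_normalized),
            "min_class_share": float(self.min_class_share),
            "min_mean_posterior": float(np.nanmin(self.mean_posterior_per_class)),
        }
        if self.boot_lrt_p is not None:
            d["boot_lrt_p"] = float(self.boot_lrt_p)
        return d


# ---------------------------------------------------------------------------
# Likelihood machinery
# ---------------------------------------------------------------------------


def _log_components(pi: np.ndarray, rhos: list[np.ndarray], codes: np.ndarray) -> np.ndarray:
    """log(pi_c) + sum_j log rho_{j,c,y_j} for each row of ``codes`` -> (n, K)."""
    L = np.broadcast_to(
        np.log(np.maximum(pi, _RHO_FLOOR)), (codes.shape[0], len(pi))
    ).copy()
    for j, rho in enumerate(rhos):
        L += np.log(np.maximum(rho, _RHO_FLOOR)).T[codes[:, j], :]
    return L


def _prepare(cohort: Cohort):
    codes, sizes = indicator_codes(cohort)
    names = list(cohort.levels.keys())
    degenerate = tuple(
        names[j] for j in range(codes.shape[1]) if len(np.unique(codes[:, j])) < 2
    )
    if degenerate:
        warnings.warn(
            f"indicator(s) {list(degenerate)} have a single observed level; "
            "they contribute nothing to the likelihood",
            stacklevel=3,
        )
    return codes, sizes, names, degenerate


def _em_single(patterns, counts, sizes, K, rng, max_iter, tol):
    """One EM run from a random Dirichlet(1) start, on aggregated patterns."""
    n_total = counts.sum()
    pi = rng.dirichlet(np.ones(K))
    rhos = [rng.dirichlet(np.ones(m), size=K) for m in sizes]

    trace: list[float] = []
    prev = -np.inf
    converged = False
    for _ in range(max_iter):
        L = _log_components(pi, rhos, patterns)
        norm = logsumexp(L, axis=1)
        ll = float(counts @ norm)
        trace.append(ll)
        if trace and ll - prev < tol and len(trace) > 1:
            converged = True
            break
        prev = ll
        theta = np.exp(L - norm[:, None])
        wc = counts[:, None] * theta  # (P, K) expected pattern counts per class
        Nk = wc.sum(axis=0)
        pi = Nk / n_total
        safe = np.maximum(Nk, _RHO_FLOOR)
        new_rhos = []
        for j, m in enumerate(sizes):
            acc = np.zeros((m, K))
            np.add.at(acc, patterns[:, j], wc)
            new_rhos.append(acc.T / safe[:, None])
        rhos = new_rhos

    if not converged:
        # params moved past the last recorded LL; evaluate once more so the
        # stored value matches the stored parameters
        L = _log_components(pi, rhos, patterns)
        ll = float(counts @ logsumexp(L, axis=1))
        trace.append(ll)
    return pi, rhos, trace[-1], tuple(trace), converged, len(trace)


def em_fit(
    cohort: Cohort,
    n_classes: int,
    *,
    max_iter: int = 1000,
    tol: float = 1e-10,
    n_restarts: int = 30,
    seed: int = 0,
) -> LCAParameters:
    """Maximum-likelihood fit of a K-class model by EM with random restarts.

    Restart r uses ``numpy.random.default_rng(seed + r)``; the restart with
    the highest final log-likelihood wins.  The log-likelihood is
    non-decreasing within every run (EM guarantee, asserted in tests).
    """
    if n_classes < 1:
        raise ValueError("n_classes must be >= 1")
    if cohort.n < n_classes:
        raise ValueError("need at least as many observations as classes")
    codes, sizes, names, degenerate = _prepare(cohort)
    patterns, counts = np.unique(codes, axis=0, return_counts=True)
    if n_classes > len(patterns):
        raise ValueError(
            f"K={n_classes} exceeds the {len(patterns)} distinct response patterns"
        )
    counts = counts.astype(float)

    best = None
    restart_lls: list[float] = []
    for r in range(n_restarts):
        rng = np.random.default_rng(seed + r)
        res = _em_single(patterns, counts, sizes, n_classes, rng, max_iter, tol)
        restart_lls.append(res[2])
        if best is None or res[2] > best[2]:
            best = res
    pi, rhos, ll, trace, converged, n_iter = best

    return LCAParameters(
        levels={k: list(v) for k, v in cohort.levels.items()},
        class_prevalence=np.asarray(pi),
        item_response={name: rhos[j] for j, name in enumerate(names)},
        log_likelihood=ll,
        n_obs=int(counts.sum()),
        converged=converged,
        n_iterations=n_iter,
        restart_loglik=tuple(restart_lls),
        loglik_trace=trace,
        degenerate_indicators=degenerate,
    )


def _params_rhos(params: LCAParameters) -> list[np.ndarray]:
    return [params.item_response[name] for name in params.levels]


def log_likelihood(params: LCAParameters, cohort: Cohort) -> float:
    """Mixture log-likelihood of a cohort under fixed parameters (log space)."""
    codes, _ = indicator_codes(cohort.data, params.levels)
    L = _log_components(params.class_prevalence, _params_rhos(params), codes)
    return float(logsumexp(L, axis=1).sum())


def posterior(params: LCAParameters, cohort: Cohort) -> PosteriorMatrix:
    """Per-patient membership probabilities theta_ic (rows sum to 1)."""
    codes, _ = indicator_codes(cohort.data, params.levels)
    L = _log_components(params.class_prevalence, _params_rhos(params), codes)
    theta = np.exp(L - logsumexp(L, axis=1)[:, None])
    return PosteriorMatrix(theta=theta, patient_id=cohort.patient_id)


def assign_classes(post: PosteriorMatrix, cutoff: float = 0.5) -> ClassAssignment:
    """Modal labels where the maximum posterior reaches the cutoff.

    Ties at the maximum go to the lowest class index (argmax convention);
    their count is recorded.
    """
    if not 0.0 <= cutoff <= 1.0:
        raise ValueError("cutoff must lie in [0, 1]")
    max_post = post.theta.max(axis=1)
    labels = post.theta.argmax(axis=1) + 1
    labels = np.where(max_post >= cutoff, labels, UNASSIGNED)
    n_ties = int(((post.theta == max_post[:, None]).sum(axis=1) > 1).sum())
    return ClassAssignment(
        labels=labels,
        max_posterior=max_post,
        cutoff=cutoff,
        patient_id=post.patient_id,
        n_ties=n_ties,
    )


def diagnostics(
    params: LCAParameters, post: PosteriorMatrix, cutoff: float = 0.5
) -> FitDiagnostics:
    """Information criteria plus entropy / modal-share / posterior summaries."""
    n, K = post.theta.shape
    ll, p = params.log_likelihood, params.n_free_params
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(post.theta > 0, post.theta * np.log(post.theta), 0.0)
    entropy_raw = float(-plogp.sum())
    entropy_norm = 1.0 if K == 1 else 1.0 - entropy_raw / (n * np.log(K))

    assign = assign_classes(post, cutoff=cutoff)
    shares = np.array([(assign.labels == c + 1).mean() for c in range(K)])
    mean_post = np.array(
        [
            post.theta[assign.labels == c + 1, c].mean()
            if (assign.labels == c + 1).any()
            else np.nan
            for c in range(K)
        ]
    )
    return FitDiagnostics(
        n_classes=K,
        log_likelihood=ll,
        n_free_params=p,
        n_obs=n,
        aic=-2 * ll + 2 * p,
        bic=-2 * ll + p * np.log(n),
        sabic=-2 * ll + p * np.log((n + 2) / 24.0),
        entropy_raw=entropy_raw,
        entropy_normalized=float(entropy_norm),
        min_class_share=float(shares.min()),
        mean_posterior_per_class=mean_post,
    )


# ---------------------------------------------------------------------------
# Sampling from a fitted model (bootstrap / projection tests)
# ---------------------------------------------------------------------------


def sample_from_parameters(
    params: LCAParameters, n: int, rng: np.random.Generator
) -> Cohort:
    """Draw indicator data from (pi, rho); survival columns are placeholders."""
    K = params.n_classes
    z = rng.choice(K, size=n, p=params.class_prevalence / params.class_prevalence.sum())
    cols: dict[str, np.ndarray] = {
        "patient_id": np.array([f"B{i + 1:07d}" for i in range(n)])
    }
    for name, lv in params.levels.items():
        rho = params.item_response[name][z]
        cum = np.cumsum(rho, axis=1)
        codes = (rng.random(n)[:, None] > cum).sum(axis=1)
        cols[name] = np.asarray(lv, dtype=object)[np.minimum(codes, len(lv) - 1)]
    cols["time_months"] = np.zeros(n)
    cols["event"] = np.zeros(n, dtype=int)
    return Cohort(data=pd.DataFrame(cols), levels=dict(params.levels))


def bootstrap_lrt(
    cohort: Cohort,
    n_classes: int,
    n_bootstrap: int,
    seed: int = 0,
    *,
    n_restarts: int = 5,
    max_iter: int = 500,
    tol: float = 1e-8,
) -> float:
    """Parametric bootstrap p-value for K classes against K-1.

    Fits both models to the data, simulates ``n_bootstrap`` datasets from the
    fitted (K-1)-class model, refits both on each, and returns
    p = (1 + #{bootstrap LRT >= observed}) / (n_bootstrap + 1).
    """
    if n_classes < 2:
        raise ValueError("bootstrap LRT needs K >= 2")
    if n_bootstrap < 19:
        raise ValueError("n_bootstrap must be >= 19")

    fit_kw = dict(n_restarts=n_restarts, max_iter=max_iter, tol=tol)
    null_fit = em_fit(cohort, n_classes - 1, seed=seed, **fit_kw)
    alt_fit = em_fit(cohort, n_classes, seed=seed + 10_000, **fit_kw)
    observed = 2.0 * (alt_fit.log_likelihood - null_fit.log_likelihood)

    rng = np.random.default_rng(seed + 20_000)
    n_exceed = 0
    n_nonconv = 0
    for b in range(n_bootstrap):
        boot = sample_from_parameters(null_fit, cohort.n, rng)
        f0 = em_fit(boot, n_classes - 1, seed=seed + 2 * b, **fit_kw)
        f1 = em_fit(boot, n_classes, seed=seed + 2 * b + 1, **fit_kw)
        if not (f0.converged and f1.converged):
            n_nonconv += 1
        if 2.0 * (f1.log_likelihood - f0.log_likelihood) >= observed:
            n_exceed += 1
    if n_nonconv > 0.1 * n_bootstrap:
        warnings.warn(
            f"{n_nonconv} of {n_bootstrap} bootstrap replicates did not converge",
            stacklevel=2,
        )
    return (1.0 + n_exceed) / (n_bootstrap + 1.0)


# ---------------------------------------------------------------------------
# Model scan / selection
# ---------------------------------------------------------------------------


@dataclass
class SelectionRules:
    """Hard admissibility criteria and the information criterion to minimize."""

    min_entropy: float = 0.8
    min_mean_posterior: float = 0.5
    min_class_share: float = 0.05  # smallest class must EXCEED this
    #: basis for the smallest-class rule: the estimated mixing proportion
    #: ("prevalence", default) or the modal-assignment share ("modal").
    #: Modal classification shrinks small classes below their mixing
    #: proportion, so the modal basis can reject the generating model.
    share_basis: str = "prevalence"
    small_sample_n: int = 500  # below this, AIC replaces BIC
    use_bootstrap_lrt: bool = False
    lrt_bootstrap: int = 99
    lrt_alpha: float = 0.05


@dataclass
class ModelScan:
    """Per-K diagnostics, the pass/fail table and the selected class count."""

    table: pd.DataFrame
    selected_k: int | None
    fits: dict[int, LCAParameters]
    diagnostics: dict[int, FitDiagnostics]
    criterion: str


def scan_models(
    cohort: Cohort,
    k_range,
    rules: SelectionRules | None = None,
    *,
    seed: int = 0,
    n_restarts: int = 10,
    tol: float = 1e-8,
    max_iter: int = 1000,
) -> ModelScan:
    """Fit each K in ``k_range`` and select by the admissibility criteria.

    Among K passing all hard criteria (normalized entropy, mean posterior per
    class, smallest-class share, optional bootstrap LRT vs K-1), the K
    minimizing BIC (AIC when n < ``rules.small_sample_n``) is selected.
    """
    k_range = sorted(set(int(k) for k in k_range))
    if not k_range:
        raise ValueError("k_range must be non-empty")
    rules = rules or SelectionRules()
    criterion = "bic" if cohort.n >= rules.small_sample_n else "aic"

    fits: dict[int, LCAParameters] = {}
    diags: dict[int, FitDiagnostics] = {}
    rows = []
    for k in k_range:
        params = em_fit(
            cohort, k, n_restarts=n_restarts, tol=tol, max_iter=max_iter,
            seed=seed + 1000 * k,
        )
        params, _ = reorder_classes(params)
        post = posterior(params, cohort)
        diag = diagnostics(params, post)
        if rules.use_bootstrap_lrt and k >= 2:
            diag.boot_lrt_p = bootstrap_lrt(
                cohort, k, rules.lrt_bootstrap, seed=seed + 777 * k
            )
        fits[k], diags[k] = params, diag

        pass_entropy = diag.entropy_normalized >= rules.min_entropy or k == 1
        pass_post = (
            k == 1
            or (
                np.all(np.nan_to_num(diag.mean_posterior_per_class, nan=-1.0)
                       >= rules.min_mean_posterior)
            )
        )
        smallest = (
            float(params.class_prevalence.min())
            if rules.share_basis == "prevalence"
            else diag.min_class_share
        )
        pass_share = smallest > rules.min_class_share or k == 1
        pass_lrt = (
            diag.boot_lrt_p is None
            or k == 1
            or diag.boot_lrt_p < rules.lrt_alpha
        )
        rows.append(
            {
                "n_classes": k,
                **diag.to_dict(),
                "pass_entropy": pass_entropy,
                "pass_mean_posterior": bool(pass_post),
                "pass_class_share": pass_share,
                "pass_lrt": pass_lrt,
                "admissible": pass_entropy and pass_post and pass_share and pass_lrt,
            }
        )
    table = pd.DataFrame(rows)
    admissible = table[table["admissible"]]
    selected = (
        None
        if admissible.empty
        else int(admissible.loc[admissible[criterion].idxmin(), "n_classes"])
    )
    return ModelScan(
        table=table, selected_k=selected, fits=fits, diagnostics=diags,
        criterion=criterion,
    )


# ---------------------------------------------------------------------------
# Reordering and projection
# ---------------------------------------------------------------------------


def reorder_classes(
    params: LCAParameters, reference: LCAParameters | None = None
) -> tuple[LCAParameters, np.ndarray]:
    """Relabel classes canonically or against a reference model.

    Without a reference, classes are sorted by descending prevalence.  With a
    reference (same K and indicator structure), classes are matched by the
    permutation minimizing the total L1 distance between item-response
    vectors (exhaustive over the K! permutations).  Returns the relabeled
    parameters and ``order`` such that new class ``i`` is old class
    ``order[i]``.  The log-likelihood is unchanged.
    """
    K = params.n_classes
    if reference is None:
        order = np.argsort(-params.class_prevalence, kind="stable")
    else:
        if reference.n_classes != K or list(reference.levels) != list(params.levels):
            raise ValueError("reference model has a different class/indicator structure")
        best_cost, best_perm = np.inf, None
        for perm in itertools.permutations(range(K)):
            perm = np.asarray(perm)
            cost = 0.0
            for name in params.levels:
                cost += np.abs(
                    params.item_response[name][perm] - reference.item_response[name]
                ).sum()
            if cost < best_cost:
                best_cost, best_perm = cost, perm
        order = best_perm
    new = LCAParameters(
        levels={k: list(v) for k, v in params.levels.items()},
        class_prevalence=params.class_prevalence[order],
        item_response={k: v[order] for k, v in params.item_response.items()},
        log_likelihood=params.log_likelihood,
        n_obs=params.n_obs,
        converged=params.converged,
        n_iterations=params.n_iterations,
        restart_loglik=params.restart_loglik,
        loglik_trace=params.loglik_trace,
        degenerate_indicators=params.degenerate_indicators,
    )
    return new, np.asarray(order)


def project_classes(
    params: LCAParameters, new_cohort: Cohort, cutoff: float = 0.0
) -> tuple[PosteriorMatrix, ClassAssignment]:
    """Score a new cohort under a fitted model and assign modal classes.

    Projection onto an external cohort assigns every patient by the highest
    posterior (cutoff 0 by default); pass ``cutoff=0.5`` to reproduce
    training-cohort assignment behavior.  Unseen indicator levels raise.
    """
    post = posterior(params, new_cohort)
    return post, assign_classes(post, cutoff=cutoff)


def parameters_from_distributions(
    levels: dict[str, list[str]],
    class_prevalence: np.ndarray,
    item_response: dict[str, np.ndarray],
) -> LCAParameters:
    """Wrap known (pi, rho) — e.g. a generator's truth — as LCAParameters."""
    return LCAParameters(
        levels={k: list(v) for k, v in levels.items()},
        class_prevalence=np.asarray(class_prevalence, dtype=float),
        item_response={k: np.asarray(v, dtype=float) for k, v in item_response.items()},
        log_likelihood=float("nan"),
        n_obs=0,
    )
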