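"""Parameter estimation and the extended-lineage-sorting likelihood-ratio test.

Emission probabilities are estimated with the Baum-Welch (EM) algorithm, with
the exception of the external-state error rate ``eps_E`` which is held fixed at
0.01.  The mean region lengths ``l_I``, ``l_E``, ``l_ELS`` and the ELS entry
proportion ``p`` are estimated by maximizing the forward log-likelihood with a
derivative-free local optimizer (COBYLA), subject to ``l_ELS >= l_E``:
ELS regions are required to be longer, on average, than plain external
regions, otherwise the two states are not identifiable.  A full fit alternates
the two steps until the joint log-likelihood stabilizes, from several jittered
starting points.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .model import (
    EMISSION_CLAMP,
    STATE_E,
    STATE_ELS,
    STATE_I,
    InferenceError,
    ModelParams,
    SiteSequence,
    forward_backward,
    forward_loglik,
    restricted_model,
)

logger = logging.getLogger("elscan")

#: Baum-Welch defaults: at most 40 iterations, stop when the log-likelihood
#: improves by less than 1e-4.
EM_MAX_ITERS = 40
EM_TOL = 1e-4
#: length optimization defaults: at most 1000 objective evaluations, accuracy 1e-4
OPT_MAX_EVALS = 1000
OPT_TOL = 1e-4

_LOG_L_MIN, _LOG_L_MAX = np.log(1e-6), np.log(100.0)
_LOGIT_MAX = 16.0  # |logit p| bound, p in ~[1e-7, 1 - 1e-7]


@dataclass
class FitResult:
    """Outcome of a parameter-estimation run."""

    params: ModelParams
    loglik: float
    n_em_iters: int = 0
    n_opt_evals: int = 0
    converged: bool = True
    restarts: list = field(default_factory=list)
    loglik_trace: list = field(default_factory=list)


@dataclass
class LrtResult:
    """Likelihood-ratio test of the full model against the model without ELS."""

    loglik_full: float
    loglik_restricted: float
    statistic: float
    df: float
    pvalue: float
    pvalue_bonferroni: float = float("nan")


def _clamp(x: float) -> float:
    return float(np.clip(x, EMISSION_CLAMP, 1.0 - EMISSION_CLAMP))


def _seq_list(seq) -> list[SiteSequence]:
    """Normalize the ``seq`` argument: one sequence or a pool of sequences.

    Pooled fitting treats the sequences as independent chains sharing one
    parameter set (the log-likelihood is the sum over sequences) — the natural
    mode for genome-wide estimation across chromosomes or simulation suites.
    """
    seqs = [seq] if isinstance(seq, SiteSequence) else list(seq)
    if not seqs:
        raise ValueError("need at least one site sequence")
    if len({s.n_chrom for s in seqs}) != 1:
        raise ValueError("pooled sequences must share the same panel size")
    return seqs


def baum_welch_emissions(
    seq: SiteSequence | list[SiteSequence],
    params: ModelParams,
    max_iters: int = EM_MAX_ITERS,
    tol: float = EM_TOL,
    map_name: str | None = None,
) -> FitResult:
    """Re-estimate emission probabilities by expectation-maximization.

    Updates ``eps_I``, ``theta_E_fix`` and the per-bin ``theta_I`` from
    expected state-occupancy counts; ``eps_E`` is never re-estimated.  A
    frequency bin with zero expected occupancy keeps its current value (with a
    logged warning) instead of producing a NaN.
    """
    seqs = _seq_list(seq)
    params = params.copy()
    classes_l = [s.freq_classes(params.n_bins) for s in seqs]
    fixed_l = [c == params.fixed_class for c in classes_l]
    der_l = [s.archaic_derived for s in seqs]

    def decode(pars):
        tracks = [forward_backward(s, pars, map_name=map_name) for s in seqs]
        return tracks, sum(t.loglik for t in tracks)

    trace: list[float] = []
    n_iter = 0
    converged = False
    tracks, loglik = decode(params)
    for n_iter in range(1, max_iters + 1):
        wI_fix = nI_anc = wX_fix = nX_der = 0.0
        theta_w = np.zeros(params.n_bins)
        theta_n = np.zeros(params.n_bins)
        any_in_bin = np.zeros(params.n_bins, dtype=bool)
        for track, classes, fixed, der in zip(tracks, classes_l, fixed_l, der_l):
            g = track.gamma
            gI = g[:, STATE_I]
            gX = g[:, STATE_E] + g[:, STATE_ELS]  # shared external-type emissions
            wI_fix += gI[fixed].sum()
            nI_anc += gI[fixed & ~der].sum()
            wX_fix += gX[fixed].sum()
            nX_der += gX[fixed & der].sum()
            for b in range(params.n_bins):
                in_bin = classes == b
                any_in_bin[b] |= in_bin.any()
                theta_w[b] += gI[in_bin].sum()
                theta_n[b] += gI[in_bin & der].sum()
        new = params.copy()
        if wI_fix > 0:
            new.eps_I = _clamp(nI_anc / wI_fix)
        else:
            logger.warning("no expected internal occupancy at fixed sites; eps_I retained")
        if wX_fix > 0:
            new.theta_E_fix = _clamp(nX_der / wX_fix)
        else:
            logger.warning("no expected external occupancy at fixed sites; theta_E_fix retained")
        theta = new.theta_I.copy()
        for b in range(params.n_bins):
            if theta_w[b] > 0:
                theta[b] = _clamp(theta_n[b] / theta_w[b])
            elif any_in_bin[b]:
                logger.warning("empty expected counts in frequency bin %d; theta_I retained", b)
        new.theta_I = theta
        new_tracks, new_loglik = decode(new)
        if new_loglik < loglik - 1e-8:
            # EM guarantees nondecreasing likelihood; numerical regression stops the loop
            logger.warning(
                "EM log-likelihood decreased by %.3g; stopping", loglik - new_loglik
            )
            converged = True
            break
        improvement = new_loglik - loglik
        params, tracks, loglik = new, new_tracks, new_loglik
        trace.append(loglik)
        if improvement < tol:
            converged = True
            break
    return FitResult(
        params=params,
        loglik=float(loglik),
        n_em_iters=n_iter,
        converged=converged,
        loglik_trace=trace,
    )


def _pack(params: ModelParams, restricted: bool) -> np.ndarray:
    if restricted:
        return np.log([params.l_I, params.l_E])
    logit_p = np.clip(
        np.log(max(params.p, 1e-7)) - np.log(max(1.0 - params.p, 1e-7)),
        -_LOGIT_MAX,
        _LOGIT_MAX,
    )
    return np.array(
        [np.log(params.l_I), np.log(params.l_E), np.log(params.l_ELS), logit_p]
    )


def _unpack(x: np.ndarray, params: ModelParams, restricted: bool) -> ModelParams:
    if restricted:
        lI, lE = np.exp(x)
        return params.copy(l_I=float(lI), l_E=float(lE), l_ELS=float(max(lE, params.l_ELS)), p=0.0)
    lI, lE, lS = np.exp(x[:3])
    p = 1.0 / (1.0 + np.exp(-x[3]))
    return params.copy(l_I=float(lI), l_E=float(lE), l_ELS=float(max(lS, lE)), p=float(p))


def optimize_lengths(
    seq: SiteSequence | list[SiteSequence],
    params: ModelParams,
    max_evals: int = OPT_MAX_EVALS,
    tol: float = OPT_TOL,
    map_name: str | None = None,
    restricted: bool = False,
) -> FitResult:
    """Maximize the forward log-likelihood over region lengths (and ``p``).

    The search runs in transformed coordinates (log lengths, logit ``p``) with
    the constraint ``l_ELS >= l_E``.  With ``restricted=True`` only
    ``(l_I, l_E)`` are optimized and ``p`` is pinned to zero (the nested
    two-state model).
    """
    from .model import emission_matrix, loglik_given_emissions

    seqs = _seq_list(seq)
    params = params.copy(p=0.0) if restricted else params.copy()
    x0 = _pack(params, restricted)
    n_evals = 0
    # emissions are fixed during the length search: precompute them once
    pre = [
        (
            emission_matrix(params, s.freq_classes(params.n_bins), s.archaic_derived),
            s.distances(map_name) if len(s) > 1 else np.empty(0),
        )
        for s in seqs
    ]

    def objective(x):
        nonlocal n_evals
        n_evals += 1
        try:
            cand = _unpack(x, params, restricted)
            return -sum(loglik_given_emissions(em, d, cand) for em, d in pre)
        except (InferenceError, ValueError):
            return 1e12

    cons = []
    ndim = len(x0)
    for i in range(min(ndim, 3)):
        cons.append({"type": "ineq", "fun": lambda x, i=i: x[i] - _LOG_L_MIN})
        cons.append({"type": "ineq", "fun": lambda x, i=i: _LOG_L_MAX - x[i]})
    if not restricted:
        cons.append({"type": "ineq", "fun": lambda x: x[2] - x[1]})  # l_ELS >= l_E
        cons.append({"type": "ineq", "fun": lambda x: x[3] + _LOGIT_MAX})
        cons.append({"type": "ineq", "fun": lambda x: _LOGIT_MAX - x[3]})
    res = optimize.minimize(
        objective,
        x0,
        method="COBYLA",
        constraints=cons,
        tol=tol,
        options={"maxiter": max_evals, "rhobeg": 0.7},
    )
    best = _unpack(res.x, params, restricted)
    ll = sum(loglik_given_emissions(em, d, best) for em, d in pre)
    ll0 = sum(loglik_given_emissions(em, d, params) for em, d in pre)
    if ll0 > ll:  # keep best-so-far if the optimizer wandered off
        best, ll = params, ll0
    return FitResult(
        params=best,
        loglik=float(ll),
        n_opt_evals=n_evals,
        converged=bool(res.success) or n_evals < max_evals,
    )


def _jitter(params: ModelParams, rng: np.random.Generator) -> ModelParams:
    """Default restart jitter: lengths scaled by x/÷3, p shifted by ±0.2."""
    scale = lambda v: float(v * 3.0 ** rng.uniform(-1, 1))
    lE = scale(params.l_E)
    return params.copy(
        l_I=scale(params.l_I),
        l_E=lE,
        l_ELS=max(scale(params.l_ELS), lE),
        p=float(np.clip(params.p + rng.uniform(-0.2, 0.2), 1e-4, 1.0 - 1e-4)),
    )


DEFAULT_START = dict(l_I=0.012, l_E=0.0016, l_ELS=0.05, p=0.05)


def _default_start(seq: SiteSequence) -> ModelParams:
    """Starting point: neutral human-archaic expectations for region lengths,
    frequency-bin centers for the internal emission curve."""
    n_bins = 20
    theta = (np.arange(n_bins) + 0.5) / n_bins
    return ModelParams(theta_I=theta, **DEFAULT_START)


def fit(
    seq: SiteSequence | list[SiteSequence],
    init_params: ModelParams | None = None,
    n_restarts: int = 2,
    refine: bool = True,
    max_rounds: int = 5,
    joint_tol: float = 1e-4,
    seed: int = 0,
    map_name: str | None = None,
    restricted: bool = False,
    em_max_iters: int = EM_MAX_ITERS,
    opt_max_evals: int = OPT_MAX_EVALS,
) -> FitResult:
    """Joint parameter estimation.

    Each run alternates a full Baum-Welch pass over the emissions with a full
    length optimization, for at most ``max_rounds`` rounds or until the joint
    log-likelihood improves by less than ``joint_tol``.  ``n_restarts`` runs
    start from ``init_params`` and seeded jitters of it; with ``refine=True``
    the best run's parameters seed one final refinement run.
    """
    if init_params is None:
        init_params = _default_start(seq)
    rng = np.random.default_rng(seed)
    starts = [init_params] + [_jitter(init_params, rng) for _ in range(max(0, n_restarts - 1))]

    def run(start: ModelParams) -> FitResult:
        cur = start.copy(p=0.0) if restricted else start.copy()
        ll = -np.inf
        em_iters = evals = 0
        converged = False
        for _ in range(max_rounds):
            em = baum_welch_emissions(
                seq, cur, max_iters=em_max_iters, map_name=map_name
            )
            opt = optimize_lengths(
                seq, em.params, max_evals=opt_max_evals, map_name=map_name,
                restricted=restricted,
            )
            em_iters += em.n_em_iters
            evals += opt.n_opt_evals
            cur = opt.params
            if opt.loglik - ll < joint_tol:
                ll = max(ll, opt.loglik)
                converged = True
                break
            ll = opt.loglik
        return FitResult(
            params=cur, loglik=float(ll), n_em_iters=em_iters,
            n_opt_evals=evals, converged=converged,
        )

    results = [run(s) for s in starts]
    best = max(results, key=lambda r: r.loglik)
    if refine:
        final = run(best.params)
        if final.loglik >= best.loglik:
            best = final
    best.restarts = [(s, r.loglik) for s, r in zip(starts, results)]
    return best


def fit_restricted(seq: SiteSequence, **kwargs) -> FitResult:
    """Fit the nested two-state model (no ELS state, ``p = 0``)."""
    return fit(seq, restricted=True, **kwargs)


def lrt_fit(seq: SiteSequence, seed: int = 0, map_name: str | None = None,
            n_tests: int = 1, mixture: bool = False, **fit_kwargs) -> LrtResult:
    """Fit both models and run the likelihood-ratio test.

    The restricted optimum, lifted into the full parameter space (``p`` at the
    boundary, ``l_ELS = l_E``), seeds an extra full-model run so that the full
    model can never score below the nested one through optimizer noise alone.
    """
    restricted = fit(seq, restricted=True, seed=seed, map_name=map_name, **fit_kwargs)
    full = fit(seq, seed=seed, map_name=map_name, **fit_kwargs)
    if full.loglik < restricted.loglik:
        lifted = restricted.params.copy(
            p=1e-4, l_ELS=max(restricted.params.l_E, restricted.params.l_ELS)
        )
        refit_kwargs = {k: v for k, v in fit_kwargs.items()
                        if k not in ("n_restarts", "refine", "init_params")}
        refit = fit(
            seq, init_params=lifted, n_restarts=1, refine=False,
            seed=seed, map_name=map_name, **refit_kwargs,
        )
        if refit.loglik > full.loglik:
            full = refit
    if full.loglik < restricted.loglik:
        # boundary optimum: the ELS state is unused and the models coincide
        full = FitResult(
            params=restricted.params.copy(p=0.0),
            loglik=restricted.loglik,
            n_em_iters=full.n_em_iters,
            n_opt_evals=full.n_opt_evals,
            converged=full.converged,
        )
    return lrt_els(seq, full, restricted, n_tests=n_tests, mixture=mixture)


def lrt_els(
    seq: SiteSequence,
    full_fit: FitResult,
    restricted_fit: FitResult,
    df: float = 2.0,
    mixture: bool = False,
    n_tests: int = 1,
) -> LrtResult:
    """Likelihood-ratio test for the presence of the ELS state.

    Removing the ELS state removes the two parameters ``(p, l_ELS)``, hence
    ``df = 2`` by default; because ``p = 0`` lies on the boundary of the
    parameter space this is conservative.  ``mixture=True`` uses the 50:50
    chi-square(1)/chi-square(2) boundary mixture instead.  ``n_tests`` applies
    a Bonferroni correction for genome-wide use across chromosomes.
    """
    stat = 2.0 * (full_fit.loglik - restricted_fit.loglik)
    if stat < -1e-6:
        raise InferenceError(
            f"full-model likelihood below restricted model (statistic {stat:.3g}); "
            "optimizer failure"
        )
    stat = max(stat, 0.0)
    if mixture:
        pvalue = 0.5 * stats.chi2.sf(stat, 1) + 0.5 * stats.chi2.sf(stat, 2)
    else:
        pvalue = stats.chi2.sf(stat, df)
    return LrtResult(
        loglik_full=full_fit.loglik,
        loglik_restricted=restricted_fit.loglik,
        statistic=float(stat),
        df=(1.5 if mixture else df),
        pvalue=float(pvalue),
        pvalue_bonferroni=float(min(1.0, pvalue * n_tests)),
    )
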