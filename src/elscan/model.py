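"""Three-state hidden Markov model of lineage sorting along a chromosome.

The model classifies every informative site (a position that is polymorphic or
fixed derived in a panel of present-day humans, with the allele carried by an
archaic genome recorded as ancestral or derived) into one of three genealogy
states:

``I`` (internal)
    the archaic lineage falls inside the variation of the sampled humans,

``E`` (external)
    the archaic lineage is an outgroup to all sampled human lineages
    (incomplete lineage sorting resolved in favour of the human side),

``ELS`` (extended lineage sorting)
    an external genealogy belonging to an unusually long external region,
    the signature of a rapid, typically selected, fixation.

Transitions between consecutive sites depend on the genetic distance ``d``
(in cM) separating them.  Region lengths are exponential with state-specific
means ``l_k``, giving self-transition probabilities ``exp(-d / l_k)``.  The
internal state exits to ``ELS`` with probability ``p`` and to ``E`` with
probability ``1 - p``; direct transitions between ``E`` and ``ELS`` are not
allowed because the two states are statistically indistinguishable locally.

Emissions are the archaic allele (ancestral/derived) and are stratified by the
modern-human derived-allele frequency class of the site: segregating sites are
binned by frequency, fixed derived sites form their own class.  The two
external-type states share one emission distribution.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
from numba import njit

logger = logging.getLogger("elscan")

#: state indices used throughout the package
STATE_I, STATE_E, STATE_ELS = 0, 1, 2
STATE_NAMES = ("I", "E", "ELS")

#: emission probabilities are clamped to this open interval during inference
#: to avoid absorbing zeros
EMISSION_CLAMP = 1e-6

ANCESTRAL = 0
DERIVED = 1


class ParameterError(ValueError):
    """Raised for invalid model parameters (non-positive lengths, p outside [0,1], ...)."""


class DistanceError(ValueError):
    """Raised for negative or non-finite genetic distances."""


class ConfigurationError(ValueError):
    """Raised for invalid frequency-class configuration."""


class InferenceError(RuntimeError):
    """Raised when the likelihood of a sequence is exactly zero (no admissible path)."""


class InterfaceError(ValueError):
    """Raised when two aligned objects (track/sequence) disagree in length."""


@dataclass(frozen=True)
class InformativeSite:
    """A single genome position informative about lineage sorting.

    ``freq_class`` is a bin index in ``0..n_bins-1`` for segregating sites, or
    ``n_bins`` for sites where all sampled human chromosomes carry the derived
    allele (the fixed-derived class).
    """

    chrom: str
    pos: int
    freq_class: int
    archaic_derived: bool
    gpos: Mapping[str, float]


@dataclass
class SiteSequence:
    """Genome-ordered informative sites for one chromosome.

    Columns are stored as parallel arrays.  ``gpos`` maps a recombination-map
    name to the cumulative genetic position (cM) of every site under that map.
    """

    pos: np.ndarray
    derived_count: np.ndarray
    archaic_derived: np.ndarray
    n_chrom: int
    gpos: dict[str, np.ndarray]
    chrom: str = "1"
    chrom_is_X: bool = False

    def __post_init__(self) -> None:
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.derived_count = np.asarray(self.derived_count, dtype=np.int64)
        self.archaic_derived = np.asarray(self.archaic_derived, dtype=bool)
        if self.n_chrom <= 0:
            raise ParameterError("n_chrom must be positive")
        L = len(self.pos)
        if not (len(self.derived_count) == len(self.archaic_derived) == L):
            raise InterfaceError("site columns differ in length")
        if L > 1 and not np.all(np.diff(self.pos) > 0):
            raise ValueError("positions must be strictly increasing within a chromosome")
        if np.any(self.derived_count < 1) or np.any(self.derived_count > self.n_chrom):
            raise ValueError("derived_count must be in [1, n_chrom] at informative sites")
        for name, g in self.gpos.items():
            g = np.asarray(g, dtype=float)
            if len(g) != L:
                raise InterfaceError(f"gpos[{name!r}] length mismatch")
            if L > 1 and np.any(np.diff(g) < 0):
                raise ValueError(f"gpos[{name!r}] must be nondecreasing")
            self.gpos[name] = g

    def __len__(self) -> int:
        return len(self.pos)

    @property
    def map_names(self) -> list[str]:
        return list(self.gpos)

    def _map(self, map_name: str | None) -> str:
        if map_name is None:
            if len(self.gpos) != 1:
                raise ConfigurationError(
                    "map_name must be given when the sequence carries several maps"
                )
            return next(iter(self.gpos))
        if map_name not in self.gpos:
            raise ConfigurationError(f"unknown recombination map {map_name!r}")
        return map_name

    def distances(self, map_name: str | None = None) -> np.ndarray:
        """Genetic distances (cM) between consecutive sites under one map."""
        g = self.gpos[self._map(map_name)]
        d = np.diff(g)
        # cumulative positions are validated nondecreasing; clip fp noise
        return np.clip(d, 0.0, None)

    def freq_classes(self, n_bins: int) -> np.ndarray:
        """Frequency-class index per site: ``0..n_bins-1`` segregating, ``n_bins`` fixed."""
        if n_bins < 1:
            raise ConfigurationError("n_bins must be >= 1")
        cache = self.__dict__.setdefault("_class_cache", {})
        if n_bins not in cache:
            f = self.derived_count / self.n_chrom
            cls = np.minimum((f * n_bins).astype(np.int64), n_bins - 1)
            cls[self.derived_count == self.n_chrom] = n_bins
            cache[n_bins] = cls
        return cache[n_bins]

    def site(self, i: int) -> InformativeSite:
        return InformativeSite(
            chrom=self.chrom,
            pos=int(self.pos[i]),
            freq_class=-1,  # class depends on binning; see freq_classes()
            archaic_derived=bool(self.archaic_derived[i]),
            gpos={k: float(v[i]) for k, v in self.gpos.items()},
        )


@dataclass
class ModelParams:
    """All parameters of the lineage-sorting HMM.

    Lengths are mean genetic region lengths in cM.  ``p`` is the proportion of
    exits from the internal state that enter ELS.  ``eps_E`` is the probability
    of observing the derived archaic allele at a segregating site in an
    external-type region (held fixed at 0.01, an upper bound on error and
    contamination in the archaic genomes, and never re-estimated).  ``eps_I``
    is the probability of the ancestral archaic allele at a fixed-derived site
    in an internal region.  ``theta_E_fix`` is the probability of the derived
    archaic allele at fixed-derived sites in external-type regions, and
    ``theta_I`` the per-frequency-bin probabilities of the derived archaic
    allele at segregating sites in internal regions.
    """

    l_I: float
    l_E: float
    l_ELS: float
    p: float
    eps_I: float = 0.01
    theta_E_fix: float = 0.5
    theta_I: np.ndarray = field(default_factory=lambda: np.linspace(0.025, 0.975, 20))
    eps_E: float = 0.01

    def __post_init__(self) -> None:
        self.theta_I = np.asarray(self.theta_I, dtype=float)
        self.validate()

    def validate(self) -> None:
        for name in ("l_I", "l_E", "l_ELS"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ParameterError(f"{name} must be finite and > 0, got {v}")
        for name in ("p", "eps_I", "theta_E_fix", "eps_E"):
            v = getattr(self, name)
            if not np.isfinite(v) or not 0.0 <= v <= 1.0:
                raise ParameterError(f"{name} must be in [0, 1], got {v}")
        if self.theta_I.ndim != 1 or len(self.theta_I) < 1:
            raise ParameterError("theta_I must be a nonempty 1-D vector")
        if np.any(~np.isfinite(self.theta_I)) or np.any(
            (self.theta_I < 0) | (self.theta_I > 1)
        ):
            raise ParameterError("theta_I entries must be in [0, 1]")

    @property
    def n_bins(self) -> int:
        return len(self.theta_I)

    @property
    def fixed_class(self) -> int:
        return self.n_bins

    def copy(self, **changes) -> "ModelParams":
        return replace(self, **changes)

    def prob_derived(self) -> np.ndarray:
        """P(archaic derived | state, freq class), shape ``(n_bins + 1, 3)``.

        Row index is the frequency class (last row = fixed derived); columns
        follow the (I, E, ELS) state order.  The two external-type states share
        one distribution by construction.
        """
        n = self.n_bins
        out = np.empty((n + 1, 3))
        out[:n, STATE_I] = self.theta_I
        out[n, STATE_I] = 1.0 - self.eps_I
        out[:n, STATE_E] = self.eps_E
        out[n, STATE_E] = self.theta_E_fix
        out[:, STATE_ELS] = out[:, STATE_E]
        return out


def transition_matrix(params: ModelParams, d: float) -> np.ndarray:
    """Distance-dependent 3x3 transition matrix over (I, E, ELS).

    Self transitions are ``exp(-d / l_k)``; the internal state splits its exit
    probability between ELS (fraction ``p``) and E; external-type states return
    only to I.  ``d`` is the genetic distance in cM to the next site.
    """
    if not np.isfinite(d) or d < 0:
        raise DistanceError(f"genetic distance must be finite and >= 0, got {d}")
    params.validate()
    aI = np.exp(-d / params.l_I)
    aE = np.exp(-d / params.l_E)
    aS = np.exp(-d / params.l_ELS)
    p = params.p
    t = np.array(
        [
            [aI, (1.0 - p) * (1.0 - aI), p * (1.0 - aI)],
            [1.0 - aE, aE, 0.0],
            [1.0 - aS, 0.0, aS],
        ]
    )
    return t


def emission_matrix(
    params: ModelParams, classes: np.ndarray, archaic_derived: np.ndarray
) -> np.ndarray:
    """Per-site emission probabilities, shape ``(L, 3)``."""
    classes = np.asarray(classes)
    if np.any(classes < 0) or np.any(classes > params.n_bins):
        raise ConfigurationError("frequency class outside the configured binning")
    pd = params.prob_derived()[classes]  # (L, 3)
    obs = np.asarray(archaic_derived, dtype=bool)[:, None]
    return np.where(obs, pd, 1.0 - pd)


def emission_prob(
    params: ModelParams, state: int | str, freq_class: int, archaic_derived: bool
) -> float:
    """P(archaic allele | state, frequency class) for a single site."""
    if isinstance(state, str):
        state = STATE_NAMES.index(state)
    if not 0 <= freq_class <= params.n_bins:
        raise ConfigurationError(f"unknown frequency class {freq_class}")
    pd = params.prob_derived()[freq_class, state]
    return float(pd if archaic_derived else 1.0 - pd)


def restricted_model(params: ModelParams) -> ModelParams:
    """The nested model without extended lineage sorting (``p = 0``).

    With ``p = 0`` the ELS state is unreachable from I and the chain reduces to
    the two-state internal/external model with the same ``l_I`` and ``l_E``.
    """
    return params.copy(p=0.0)


def default_init(params: ModelParams) -> np.ndarray:
    """Renewal occupancy over states: time share of I, E and ELS regions.

    The chain alternates internal regions with external-type regions, a
    fraction ``p`` of which are ELS, so expected occupancy is proportional to
    ``(l_I, (1 - p) l_E, p l_ELS)``.  This is the default initial distribution
    (and the exact stationary distribution in the limit of dense sites).
    """
    w = np.array(
        [params.l_I, (1.0 - params.p) * params.l_E, params.p * params.l_ELS]
    )
    return w / w.sum()


def stationary_distribution(params: ModelParams, d: float) -> np.ndarray:
    """Exact stationary distribution of the transition matrix at distance ``d``.

    The transition graph (I-E, I-ELS, no E-ELS edge) is a tree, so the chain is
    reversible with respect to this distribution.
    """
    t = transition_matrix(params, d)
    w = np.ones(3)
    w[STATE_E] = t[STATE_I, STATE_E] / t[STATE_E, STATE_I] if t[STATE_E, STATE_I] > 0 else 0.0
    w[STATE_ELS] = (
        t[STATE_I, STATE_ELS] / t[STATE_ELS, STATE_I] if t[STATE_ELS, STATE_I] > 0 else 0.0
    )
    return w / w.sum()


@dataclass
class PosteriorTrack:
    """Per-site state posteriors and the sequence log-likelihood."""

    gamma: np.ndarray  # (L, 3), rows sum to 1
    loglik: float

    def __len__(self) -> int:
        return len(self.gamma)

    @property
    def p_els(self) -> np.ndarray:
        return self.gamma[:, STATE_ELS]

    @property
    def p_external(self) -> np.ndarray:
        """Posterior of being in either external-type state."""
        return self.gamma[:, STATE_E] + self.gamma[:, STATE_ELS]


@njit(cache=False)
def _forward(em, d, lI, lE, lS, p, init):  # pragma: no cover - exercised via wrappers
    L = em.shape[0]
    f = np.empty((L, 3))
    scales = np.empty(L)
    for k in range(3):
        f[0, k] = init[k] * em[0, k]
    c = f[0, 0] + f[0, 1] + f[0, 2]
    if not (c > 0.0) or not np.isfinite(c):
        return f, scales, 1
    for k in range(3):
        f[0, k] /= c
    scales[0] = c
    for i in range(1, L):
        aI = np.exp(-d[i - 1] / lI)
        aE = np.exp(-d[i - 1] / lE)
        aS = np.exp(-d[i - 1] / lS)
        fI = (f[i - 1, 0] * aI + f[i - 1, 1] * (1.0 - aE) + f[i - 1, 2] * (1.0 - aS)) * em[i, 0]
        fE = (f[i - 1, 0] * (1.0 - p) * (1.0 - aI) + f[i - 1, 1] * aE) * em[i, 1]
        fS = (f[i - 1, 0] * p * (1.0 - aI) + f[i - 1, 2] * aS) * em[i, 2]
        c = fI + fE + fS
        if not (c > 0.0) or not np.isfinite(c):
            return f, scales, i + 1
        f[i, 0] = fI / c
        f[i, 1] = fE / c
        f[i, 2] = fS / c
        scales[i] = c
    return f, scales, -1


@njit(cache=False)
def _backward_gamma(em, d, lI, lE, lS, p, f, scales):  # pragma: no cover
    L = em.shape[0]
    gamma = np.empty((L, 3))
    b0 = 1.0
    b1 = 1.0
    b2 = 1.0
    s = f[L - 1, 0] + f[L - 1, 1] + f[L - 1, 2]
    for k in range(3):
        gamma[L - 1, k] = f[L - 1, k] / s
    for i in range(L - 2, -1, -1):
        aI = np.exp(-d[i] / lI)
        aE = np.exp(-d[i] / lE)
        aS = np.exp(-d[i] / lS)
        e0 = em[i + 1, 0] * b0
        e1 = em[i + 1, 1] * b1
        e2 = em[i + 1, 2] * b2
        nb0 = (aI * e0 + (1.0 - p) * (1.0 - aI) * e1 + p * (1.0 - aI) * e2) / scales[i + 1]
        nb1 = ((1.0 - aE) * e0 + aE * e1) / scales[i + 1]
        nb2 = ((1.0 - aS) * e0 + aS * e2) / scales[i + 1]
        b0, b1, b2 = nb0, nb1, nb2
        g0 = f[i, 0] * b0
        g1 = f[i, 1] * b1
        g2 = f[i, 2] * b2
        s = g0 + g1 + g2
        gamma[i, 0] = g0 / s
        gamma[i, 1] = g1 / s
        gamma[i, 2] = g2 / s
    return gamma


def _prepare(seq: SiteSequence, params: ModelParams, map_name: str | None, init):
    classes = seq.freq_classes(params.n_bins)
    em = emission_matrix(params, classes, seq.archaic_derived)
    d = seq.distances(map_name) if len(seq) > 1 else np.empty(0)
    if init is None:
        init = default_init(params)
    init = np.asarray(init, dtype=float)
    if init.shape != (3,) or np.any(init < 0) or not np.isclose(init.sum(), 1.0):
        raise ParameterError("init must be a length-3 probability vector")
    return em, d, init


def loglik_given_emissions(
    em: np.ndarray, d: np.ndarray, params: ModelParams, init: np.ndarray | None = None
) -> float:
    """Forward log-likelihood with a precomputed emission matrix.

    Fast path for optimizers that vary only the transition parameters: the
    per-site emission matrix does not change and need not be rebuilt.
    """
    if init is None:
        init = default_init(params)
    _, scales, bad = _forward(em, d, params.l_I, params.l_E, params.l_ELS, params.p, init)
    if bad >= 0:
        raise InferenceError(
            f"sequence has zero probability under the model; first impossible site index {bad - 1}"
        )
    return float(np.log(scales).sum())


def forward_loglik(
    seq: SiteSequence,
    params: ModelParams,
    init: np.ndarray | None = None,
    map_name: str | None = None,
) -> float:
    """Log-likelihood of the observation sequence under the model (forward algorithm)."""
    if len(seq) == 0:
        raise InferenceError("empty site sequence")
    em, d, init = _prepare(seq, params, map_name, init)
    _, scales, bad = _forward(em, d, params.l_I, params.l_E, params.l_ELS, params.p, init)
    if bad >= 0:
        raise InferenceError(
            f"sequence has zero probability under the model; first impossible site index {bad - 1}"
        )
    return float(np.log(scales).sum())


def forward_backward(
    seq: SiteSequence,
    params: ModelParams,
    init: np.ndarray | None = None,
    map_name: str | None = None,
) -> PosteriorTrack:
    """Posterior state probabilities per site (scaled forward-backward).

    Uses per-site scaling so that sequences of millions of sites remain
    numerically stable; the log-likelihood is the sum of log scaling factors.
    """
    if len(seq) == 0:
        raise InferenceError("empty site sequence")
    em, d, init = _prepare(seq, params, map_name, init)
    f, scales, bad = _forward(em, d, params.l_I, params.l_E, params.l_ELS, params.p, init)
    if bad >= 0:
        raise InferenceError(
            f"sequence has zero probability under the model; first impossible site index {bad - 1}"
        )
    gamma = _backward_gamma(
        em, d, params.l_I, params.l_E, params.l_ELS, params.p, f, scales
    )
    return PosteriorTrack(gamma=gamma, loglik=float(np.log(scales).sum()))
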