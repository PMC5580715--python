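"""Independent brute-force references used by the test suite.

Everything here is written directly from the model definition (exponential
region lengths, hub-and-spoke transitions, frequency-stratified emissions)
without importing the package's forward-backward machinery, so it can serve
as an oracle for it.  Only usable for tiny sequences (enumerates all 3^L or
2^L state paths).
"""

import itertools

import numpy as np


def oracle_transition(params, d):
    """3x3 transition matrix over (I, E, ELS) from the defining formulas."""
    aI = np.exp(-d / params.l_I)
    aE = np.exp(-d / params.l_E)
    aS = np.exp(-d / params.l_ELS)
    p = params.p
    return np.array(
        [
            [aI, (1 - p) * (1 - aI), p * (1 - aI)],
            [1 - aE, aE, 0.0],
            [1 - aS, 0.0, aS],
        ]
    )


def oracle_emission(params, freq_class, archaic_derived, state):
    """P(observed archaic allele | state, frequency class)."""
    n_bins = len(params.theta_I)
    if state == 0:  # internal
        p_der = params.theta_I[freq_class] if freq_class < n_bins else 1 - params.eps_I
    else:  # either external-type state
        p_der = params.eps_E if freq_class < n_bins else params.theta_E_fix
    return p_der if archaic_derived else 1 - p_der


def path_likelihoods(seq, params, init, n_states=3):
    """Joint probability of every state path; returns (paths, probs)."""
    L = len(seq)
    classes = seq.freq_classes(params.n_bins)
    d = np.diff(seq.gpos[next(iter(seq.gpos))])
    paths = list(itertools.product(range(n_states), repeat=L))
    probs = []
    for path in paths:
        pr = init[path[0]] * oracle_emission(
            params, classes[0], seq.archaic_derived[0], path[0]
        )
        for i in range(1, L):
            t = oracle_transition(params, d[i - 1])
            pr *= t[path[i - 1], path[i]] * oracle_emission(
                params, classes[i], seq.archaic_derived[i], path[i]
            )
        probs.append(pr)
    return paths, np.array(probs)


def brute_force_loglik(seq, params, init):
    _, probs = path_likelihoods(seq, params, init)
    return np.log(probs.sum())


def brute_force_posteriors(seq, params, init):
    paths, probs = path_likelihoods(seq, params, init)
    L = len(seq)
    post = np.zeros((L, 3))
    for path, pr in zip(paths, probs):
        for i, k in enumerate(path):
            post[i, k] += pr
    return post / probs.sum()


def brute_force_two_state_loglik(seq, params, init2):
    """Pure {internal, external} chain sharing l_I, l_E and the emissions."""
    L = len(seq)
    classes = seq.freq_classes(params.n_bins)
    d = np.diff(seq.gpos[next(iter(seq.gpos))])
    total = 0.0
    for path in itertools.product(range(2), repeat=L):
        pr = init2[path[0]] * oracle_emission(
            params, classes[0], seq.archaic_derived[0], path[0]
        )
        for i in range(1, L):
            aI = np.exp(-d[i - 1] / params.l_I)
            aE = np.exp(-d[i - 1] / params.l_E)
            t2 = np.array([[aI, 1 - aI], [1 - aE, aE]])
            pr *= t2[path[i - 1], path[i]] * oracle_emission(
                params, classes[i], seq.archaic_derived[i], path[i]
            )
        total += pr
    return np.log(total)
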