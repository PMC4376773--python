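"""Spiking cortical model (SCM) network and time-matrix construction.

The SCM is a simplified pulse-coupled neural network in which every pixel of
a normalized image is a neuron with internal activity ``U``, dynamic
threshold ``E`` and binary output ``Y``. Per iteration ``n``::

    U(n) = f * U(n-1) + S * sum_kl[ W_kl * Y_kl(n-1) ] + S     (activity)
    Y(n) = 1  if U(n) > E(n-1) else 0                          (output)
    E(n) = g * E(n-1) + h * Y(n)                               (threshold)

where ``S`` is the stimulus (pixel intensity in [0, 1]) and the sum runs
over the 8-neighbourhood weighted by the coupling kernel ``W``. The network
is modified to be single-shot: once a neuron fires, its output is frozen at
zero and its state is no longer updated. Recording the iteration at which
each neuron first fires yields the *time matrix*, a composite image in which
bright, spatially coherent features occupy the early iterations and dim
features (background, artifacts) the late ones.

With the default coefficients a silent neuron's threshold grows as
``g**n`` while its activity saturates at ``S / (1 - f)``; stimuli below
``min_n g**(n-1) * (1 - f) / (1 - f**n)`` (about 0.268) never fire at all
and receive the sentinel value ``max_iter + 1``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator

import numpy as np
from scipy.ndimage import correlate

from .config import SCMParameters
from .errors import DataError, ShapeMismatchError

__all__ = [
    "SCMState",
    "initial_state",
    "scm_iterate",
    "iter_pulse_outputs",
    "compute_time_matrix",
    "scalar_firing_time",
]


@dataclass
class SCMState:
    """Per-pixel state of the network at iteration ``n``.

    ``Y`` holds the *current* iteration's pulse output; ``fired`` marks
    neurons that have pulsed at any iteration up to and including ``n``.
    """

    U: np.ndarray
    E: np.ndarray
    Y: np.ndarray
    fired: np.ndarray
    n: int = 0


def initial_state(shape: tuple[int, int]) -> SCMState:
    """Quiescent network state: U=0, Y=0, E=1, nothing fired.

    E(0)=1 (the top of the normalized intensity range) makes the brightest
    pixels fire first; starting the threshold at zero would fire every
    neuron in the first iteration and collapse the time matrix.
    """
    return SCMState(
        U=np.zeros(shape, dtype=np.float64),
        E=np.ones(shape, dtype=np.float64),
        Y=np.zeros(shape, dtype=bool),
        fired=np.zeros(shape, dtype=bool),
        n=0,
    )


def _check_stimulus(S: np.ndarray) -> np.ndarray:
    S = np.asarray(S, dtype=np.float64)
    if S.ndim != 2:
        raise DataError(f"stimulus must be 2-D, got ndim={S.ndim}")
    if S.size and (S.min() < 0.0 or S.max() > 1.0):
        raise DataError(
            "stimulus must be normalized to [0, 1]; "
            f"got range [{S.min():.4g}, {S.max():.4g}]"
        )
    return S


def scm_iterate(state: SCMState, S: np.ndarray,
                params: SCMParameters) -> SCMState:
    """Advance the network by one iteration (in place) and return the state.

    Out-of-frame neighbours contribute zero (zero padding). Neurons that
    fired in an earlier iteration keep their U and E frozen and contribute
    Y = 0 to their neighbours.
    """
    S = _check_stimulus(S)
    if state.U.shape != S.shape:
        raise ShapeMismatchError(
            f"state shape {state.U.shape} != stimulus shape {S.shape}"
        )
    # Neighbour input from the previous iteration's pulses, zero-padded.
    coupling = correlate(state.Y.astype(np.float64), params.kernel,
                         mode="constant", cval=0.0)
    live = ~state.fired
    U = params.f * state.U + S * coupling + S
    fire = (U > state.E) & live
    E = params.g * state.E + params.h * fire
    # Freeze state of neurons that had already fired before this iteration.
    state.U = np.where(live, U, state.U)
    state.E = np.where(live, E, state.E)
    state.Y = fire
    state.fired = state.fired | fire
    state.n += 1
    return state


def iter_pulse_outputs(S: np.ndarray, params: SCMParameters,
                       n_iters: int) -> Iterator[np.ndarray]:
    """Yield the binary pulse output of iterations 1..n_iters.

    The pulse outputs are pairwise disjoint because each neuron fires at
    most once.
    """
    S = _check_stimulus(S)
    state = initial_state(S.shape)
    for _ in range(n_iters):
        scm_iterate(state, S, params)
        yield state.Y.copy()
        if state.fired.all():
            break


def compute_time_matrix(S: np.ndarray,
                        params: SCMParameters) -> np.ndarray:
    """First-pulse iteration index per pixel (the time matrix).

    Runs the network until every neuron has fired or ``max_iter`` is
    reached. Pixels that never fire receive the sentinel ``max_iter + 1``.
    Brighter pixels fire earlier, so the time matrix is an intensity-ordered
    relabelling of the image: its regional minima sit on the brightest
    coherent features.
    """
    S = _check_stimulus(S)
    state = initial_state(S.shape)
    tm = np.full(S.shape, params.sentinel, dtype=np.int32)
    for _ in range(params.max_iter):
        scm_iterate(state, S, params)
        tm[state.Y] = state.n
        if state.fired.all():
            break
    return tm


def scalar_firing_time(s: float, params: SCMParameters,
                       coupling: float = 0.0) -> int:
    """Firing iteration of one isolated neuron with stimulus ``s``.

    Direct evaluation of the scalar recurrence (``coupling`` is a constant
    neighbour term added to U each iteration, zero for an isolated neuron).
    Returns the sentinel if the neuron never fires within ``max_iter``.
    Used as an independent oracle for the array implementation.
    """
    u, e = 0.0, 1.0
    for n in range(1, params.max_iter + 1):
        u = params.f * u + s * coupling + s
        if u > e:
            return n
        e = params.g * e
    return params.sentinel
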