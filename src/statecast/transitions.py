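"""Four-class transition encoding of binary clinical state sequences.

A patient's circulatory state over a regular time grid is a binary sequence
``s_1 .. s_T`` (0 = stable, 1 = circulatory failure).  Rather than forecast
the raw 0/1 state, the transition representation classifies each consecutive
pair ``(s_t, s_{t+1})`` into one of four classes:

====  =================  ==================
code  meaning            pair
====  =================  ==================
0     stay stable        (0, 0)
1     recovery           (1, 0)
2     onset              (0, 1)
3     stay in failure    (1, 1)
====  =================  ==================

The last observation has no successor, so an encoded sequence is one element
shorter than its source and element ``t`` describes ``(s_t, s_{t+1})``.

Decoding maps a (possibly incoherent, e.g. model-predicted) class sequence
back to 0/1 states.  Two conventions exist because each class pins down both
the current and the next state:

* ``"current"`` (default): classes {1, 3} -> 1, i.e. the decoded label at
  target index t is the state *at* t, directly comparable to ``s_t``.
* ``"next"``: classes {2, 3} -> 1, i.e. the state one step after the target.

Evaluation compares decoded predictions at target time t against ``s_t``,
which is what the ``"current"`` convention produces.
"""

from __future__ import annotations

import numpy as np

from .errors import InputError

#: valid transition class codes
TRANSITION_CLASSES = (0, 1, 2, 3)

#: decode conventions -> the two classes mapping to state 1
_CONVENTIONS = {
    "current": (1, 3),
    "next": (2, 3),
}


def _as_int_array(values, name: str) -> np.ndarray:
    arr = np.asarray(values)
    if arr.ndim != 1:
        raise InputError(f"{name} must be one-dimensional, got shape {arr.shape}")
    if arr.size and not np.all(np.isin(arr, [0, 1, 2, 3])):
        raise InputError(f"{name} contains values outside the expected code set")
    return arr.astype(np.int64)


def encode_transitions(states) -> np.ndarray:
    """Encode a binary state sequence into transition classes.

    Parameters
    ----------
    states : array-like of {0, 1}, length T >= 2

    Returns
    -------
    numpy.ndarray of {0, 1, 2, 3}, length T - 1
        Element t encodes the pair ``(s_t, s_{t+1})``.
    """
    s = np.asarray(states)
    if s.ndim != 1 or s.size < 2:
        raise InputError("states must be a 1-D sequence of length >= 2")
    if not np.all(np.isin(s, [0, 1])):
        raise InputError("states must be binary (0/1)")
    s = s.astype(np.int64)
    # (0,0)->0, (1,0)->1, (0,1)->2, (1,1)->3
    return s[:-1] + 2 * s[1:]


def decode_states(transitions, convention: str = "current") -> np.ndarray:
    """Map transition classes back to binary states.

    Works on arbitrary class sequences — predictions need not be coherent
    (element t's implied next state may disagree with element t+1's implied
    current state); each element is decoded independently.
    """
    codes = _as_int_array(transitions, "transitions")
    try:
        ones = _CONVENTIONS[convention]
    except KeyError:
        raise InputError(
            f"unknown decode convention {convention!r}; expected 'current' or 'next'"
        ) from None
    return np.isin(codes, ones).astype(np.int64)


def score_state1(class_probabilities, convention: str = "current", tol: float = 1e-9):
    """Collapse 4-class probabilities to the probability of state 1.

    Under the ``"current"`` convention this is P(class 1) + P(class 3); under
    ``"next"`` it is P(class 2) + P(class 3).  Accepts a single length-4
    vector or an (n, 4) matrix; rows must be non-negative and sum to 1
    within ``tol``.
    """
    p = np.asarray(class_probabilities, dtype=float)
    single = p.ndim == 1
    if single:
        p = p[None, :]
    if p.ndim != 2 or p.shape[1] != 4:
        raise InputError("class_probabilities must have 4 columns")
    if np.any(p < 0):
        raise InputError("class probabilities must be non-negative")
    if np.any(np.abs(p.sum(axis=1) - 1.0) > tol):
        raise InputError(f"class probability rows must sum to 1 within {tol}")
    try:
        a, b = _CONVENTIONS[convention]
    except KeyError:
        raise InputError(
            f"unknown decode convention {convention!r}; expected 'current' or 'next'"
        ) from None
    out = p[:, a] + p[:, b]
    return float(out[0]) if single else out
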