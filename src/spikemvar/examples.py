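"""Canonical example models: the package's reference connectivity motifs.

Three small propagation-form MVAR models with unit innovation covariance,
used throughout the tests and the demo: a unidirectional pair (channel 0
drives channel 1 at lag 2), a sequential triple (0 -> 1 -> 2 with a lag-2
link into channel 2), and a common-input triple (channel 0 drives channels 1
and 2 with different delays).  Ground-truth directed edges are exposed
alongside each model as ``(source, target)`` pairs (0-based).
"""

from __future__ import annotations

import numpy as np

from .mvar_core import MVARModel

__all__ = [
    "unidirectional_pair",
    "sequential_triple",
    "common_input_triple",
    "TRUE_EDGES",
]


def unidirectional_pair() -> MVARModel:
    """Bivariate order-2 model: 0 -> 1 via a lag-2 coupling of strength -1/2."""
    B1 = [[0.5, 0.0], [0.0, 0.5]]
    B2 = [[0.0, 0.0], [-0.5, 0.0]]
    return MVARModel.from_propagation([B1, B2], np.eye(2))


def sequential_triple() -> MVARModel:
    """Trivariate order-3 chain 0 -> 1 -> 2.

    Channel 0 drives 1 at lag 1, channel 1 drives 2 at lag 2; channel 0 has
    an additional lag-3 self term.
    """
    B1 = [[0.5, 0.0, 0.0], [0.5, 0.5, 0.0], [0.0, 0.0, 0.5]]
    B2 = [[0.0, 0.0, 0.0], [0.0, 0.0, 0.0], [0.0, -0.5, 0.0]]
    B3 = [[-0.5, 0.0, 0.0], [0.0, 0.0, 0.0], [0.0, 0.0, 0.0]]
    return MVARModel.from_propagation([B1, B2, B3], np.eye(3))


def common_input_triple() -> MVARModel:
    """Trivariate order-3 fork: 0 drives 1 (lag 1) and 2 (lag 3)."""
    B1 = [[0.5, 0.0, 0.0], [0.5, 0.5, 0.0], [0.0, 0.0, 0.5]]
    B2 = np.zeros((3, 3))
    B3 = [[-0.5, 0.0, 0.0], [0.0, 0.0, 0.0], [-0.5, 0.0, 0.0]]
    return MVARModel.from_propagation([B1, B2, B3], np.eye(3))


#: ground-truth directed edges of each example, as (source, target) pairs
TRUE_EDGES = {
    "unidirectional_pair": {(0, 1)},
    "sequential_triple": {(0, 1), (1, 2)},
    "common_input_triple": {(0, 1), (0, 2)},
}
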