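"""Frozen commutator and adjoint tables of the five-dimensional algebra.

Entry (m, n) of COMMUTATOR_TABLE is the coefficient vector of [Y_m, Y_n]
over (Y1..Y5); missing keys are zero.  Entry (m, n) of ADJOINT_TABLE is
Ad(e^{eps Y_m}) Y_n; missing keys are the unchanged Y_n.
"""

import sympy as sp

from dnalie.algebra_tools import epsilon as e
from dnalie.model_core import alpha, gamma

A2G = alpha**2 / gamma

COMMUTATOR_TABLE = {
    (1, 4): (0, 1, 0, 0, 0),
    (1, 5): (1, 0, 0, 0, 0),
    (2, 5): (0, -2, 0, 0, 0),
    (3, 5): (0, -A2G, 0, 0, 0),
    (4, 1): (0, -1, 0, 0, 0),
    (4, 5): (0, 0, 0, -3, 0),
    (5, 1): (-1, 0, 0, 0, 0),
    (5, 2): (0, 2, 0, 0, 0),
    (5, 3): (0, A2G, 0, 0, 0),
    (5, 4): (0, 0, 0, 3, 0),
}

ADJOINT_TABLE = {
    (1, 4): (0, -e, 0, 1, 0),
    (1, 5): (-e, 0, 0, 0, 1),
    (2, 5): (0, 2 * e, 0, 0, 1),
    (3, 5): (0, A2G * e, 0, 0, 1),
    (4, 1): (1, e, 0, 0, 0),
    (4, 5): (0, 0, 0, 3 * e, 1),
    (5, 1): (sp.exp(e), 0, 0, 0, 0),
    (5, 2): (0, sp.exp(-2 * e), 0, 0, 0),
    (5, 3): (0, alpha**2 / (2 * gamma) * (-1 + sp.exp(-2 * e)), 1, 0, 0),
    (5, 4): (0, 0, 0, sp.exp(-3 * e), 0),
}
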