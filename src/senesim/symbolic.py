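"""Symbolic kinetics: exact Jacobians and parameter derivatives via sympy.

Used by the Lyapunov machinery (tangent-space dynamics need an analytic
Jacobian because the calibrated network is stiff) and by the variational
sensitivity oracle.  Input levels are treated as fixed symbols, so the
generated functions are valid within one piecewise-constant input segment.
"""

from __future__ import annotations

import numpy as np
import sympy as sp

from .network import NetworkModel

__all__ = ["symbolic_system", "lambdified_system"]


def symbolic_system(model: NetworkModel):
    """Symbolic state vector, parameter vector, input vector and rhs."""
    x = sp.Matrix([sp.Symbol(f"x_{s.id}", nonnegative=True) for s in model.species])
    k = sp.Matrix([sp.Symbol(f"p_{r.id}", nonnegative=True) for r in model.reactions])
    u = sp.Matrix([sp.Symbol(f"u_{i}", nonnegative=True) for i in range(len(model.inputs))])
    input_index = {sig.name: i for i, sig in enumerate(model.inputs)}

    rates = []
    for j, r in enumerate(model.reactions):
        expr = k[j]
        for sid, sto in r.reactants.items():
            expr *= x[model.species_index[sid]] ** sto
        for m in r.modifiers:
            if m in model.species_index:
                expr *= x[model.species_index[m]]
            else:
                expr *= u[input_index[m]]
        rates.append(expr)
    S = sp.Matrix(model.stoichiometry.astype(int))
    f = S * sp.Matrix(rates)
    return x, k, u, f


def lambdified_system(model: NetworkModel):
    """Fast callables ``f(x, k, u)``, ``jac_x(x, k, u)``, ``jac_k(x, k, u)``."""
    x, k, u, f = symbolic_system(model)
    Jx = f.jacobian(x)
    Jk = f.jacobian(k)
    args = (list(x), list(k), list(u))
    f_fn = sp.lambdify(args, list(f), modules="numpy")
    jx_fn = sp.lambdify(args, Jx, modules="numpy")
    jk_fn = sp.lambdify(args, Jk, modules="numpy")

    def f_num(xv, kv, uv):
        return np.asarray(f_fn(list(xv), list(kv), list(uv)), dtype=float)

    def jx_num(xv, kv, uv):
        return np.asarray(jx_fn(list(xv), list(kv), list(uv)), dtype=float)

    def jk_num(xv, kv, uv):
        return np.asarray(jk_fn(list(xv), list(kv), list(uv)), dtype=float)

    return f_num, jx_num, jk_num
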