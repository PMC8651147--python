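"""Regenerate src/pogo/_kernels.py (exact-derivative kernels for the stance NLP).

Requires sympy (``pip install pogo[codegen]``). Run from the repository root:

    python scripts/generate_kernels.py

The symbolic model must match pogo.dynamics; see docs/methods.md.
"""
import time
import sympy as sp

t0 = time.time()

X = sp.symbols("x y vx vy q q1 q2 u", real=True)
x, y, vx, vy, q, q1, q2, u = X
k, c, eps, etp, etn, wd, wr = sp.symbols("k c eps etp etn wd wr", positive=True)
W = sp.symbols("w0:7", real=True)

Ll = sp.sqrt(x * x + y * y)
dLl = (x * vx + y * vy) / Ll
delta = 1 - Ll + q
ddelta = q1 - dLl
sig = (1 + sp.tanh(ddelta / (2 * wd))) / 2
F = k * delta + c * ddelta * sig
ax = F * x / Ll
ay = F * y / Ll - 1
ddLl = (vx**2 + vy**2 + x * ax + y * ay - dLl**2) / Ll
dddelta = q2 - ddLl
dsig = sig * (1 - sig) / wd
dF = k * ddelta + c * dddelta * sig + c * ddelta * dsig * dddelta

f = sp.Matrix([vx, vy, ax, ay, q1, q2, u])
P = F * q1
Pp = (P + sp.sqrt(P * P + wr * wr)) / 2
Pn = P - Pp
ell = Pp / etp + Pn / etn + eps * dF**2
phi = sum(W[i] * f[i] for i in range(7))

Xv = sp.Matrix(X)
args = list(X) + [k, c, eps, etp, etn, wd, wr]
argsW = args + list(W)


def tri(mat_fn):
    return [mat_fn(i, j) for i in range(8) for j in range(i, 8)]


specs = []
specs.append(("dyn", list(f) + [F, dF, delta, ddelta, Ll, ell], args))
specs.append(("jac_dyn", [sp.diff(f[i], Xv[j]) for i in range(7) for j in range(8)], args))
specs.append(("grad_ell", [sp.diff(ell, v) for v in X], args))
specs.append(("hess_ell", tri(lambda i, j: sp.diff(ell, X[i], X[j])), args))
specs.append(("grad_phi", [sp.diff(phi, v) for v in X], argsW))
specs.append(("hess_phi", tri(lambda i, j: sp.diff(phi, X[i], X[j])), argsW))
specs.append(("grad_F", [sp.diff(F, v) for v in X], args))
specs.append(("hess_F", tri(lambda i, j: sp.diff(F, X[i], X[j])), args))
specs.append(("grad_Ll", [sp.diff(Ll, v) for v in X], args))
specs.append(("hess_Ll", tri(lambda i, j: sp.diff(Ll, X[i], X[j])), args))
print("diff done", time.time() - t0)

HEADER = """\"\"\"Exact-derivative kernels for the stance collocation NLP.

Auto-generated by ``scripts/generate_kernels.py``; do not edit by hand.

Node variables (normalized units, M = g = L = 1): x, y, vx, vy are CoM
position/velocity relative to the stance foot; q, q1, q2 are the actuator
displacement from its nominal length and its first two time derivatives;
u is the actuator jerk (the control). Parameters: k spring stiffness,
c damping coefficient, eps force-rate cost coefficient, etp/etn signed
positive/negative work efficiencies, wd damper-switch smoothing width
(velocity units), wr power-rectification smoothing width (power units).

Functions are vectorized over collocation nodes: node variables may be
numpy arrays of equal shape. ``hess_*`` return the upper triangle of the
8x8 node Hessian row-major; ``grad_phi``/``hess_phi`` differentiate the
multiplier-weighted dynamics w0*f0 + ... + w6*f6.
\"\"\"
import numpy as np

"""
chunks = [HEADER]
for name, exprs, fargs in specs:
    reps, reduced = sp.cse(exprs, optimizations="basic")
    lines = [f"def {name}({', '.join(map(str, fargs))}):"]
    for s, e in reps:
        lines.append(f"    {s} = {sp.printing.pycode(e)}")
    outs = ",\n            ".join(sp.printing.pycode(e) for e in reduced)
    lines.append(f"    return [{outs}]")
    chunks.append("\n".join(lines).replace("math.", "np.") + "\n\n")
    print(name, "done", time.time() - t0)

src = "\n".join(chunks)
import os
out = os.path.join(os.path.dirname(__file__), "..", "src", "pogo", "_kernels.py")
with open(out, "w") as fh:
    fh.write(src)
print("bytes:", len(src))
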