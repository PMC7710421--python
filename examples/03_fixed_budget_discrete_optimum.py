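"""Which integer network encodes the most within a fixed energy budget?

With fc = 1 the total cost of a network is N + r*A.  Fixing the budget to the
window [154, 156) and enumerating every integer (N, A) inside it, exact
big-integer comparison of C(N, A) finds the capacity maximizer — no
approximation anywhere.
"""

from sparsenergy import CostWindow, find_discrete_optimum

window = CostWindow(154.0, 156.0)
print("  r    N    A     p      cost   log10(cap)  candidates")
for r in (1.4, 1.6, 1.8, 2.0):
    opt = find_discrete_optimum(r, window)
    print(
        f" {r:.1f}  {opt.net.N:3d}  {opt.net.A:3d}  {100 * opt.net.p:5.1f}%  "
        f"{opt.cost:6.1f}   {opt.capacity.log_value:8.4f}   {opt.n_candidates:5d}"
    )

# The optimal sparseness lands at 31-36% for every calibrated ratio: the
# energy-optimal code is sparse, but far from maximally sparse.
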