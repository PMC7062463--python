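"""Choose the number of subunits by cross-validated likelihood.

Fits the 3-subunit toy cell with N = 1..6 subunits on repeated random
train/validation splits (shared across the grid so comparisons are
paired) and reports the mean validation log-likelihood per N.  The
curve rises until the true count and falls beyond it as extra subunits
fit noise.
"""

import stclust as sc
from stclust.evaluate import select_model

cell = sc.toy_cell(3, dims=(4, 4), seed=51)
X = sc.gaussian_stimulus(200000, (4, 4), seed=52)
Y = cell.responses(X, seed=53)

n_best, lam_best, table = select_model(X, Y, n_grid=range(1, 7),
                                       repeats=3, seed=54)
print(" N   mean validation ll/bin")
for (n, lam), ll in sorted(table.items()):
    marker = "  <- selected" if n == n_best else ""
    print(f" {n}   {ll:+.5f}{marker}")
print(f"selected N* = {n_best} (true number of subunits: 3)")
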