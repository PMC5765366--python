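"""When does spatial modeling pay off?  A miniature simulation grid.

Runs the trial simulator over two spatial-fraction levels at low
heritability with a Gaussian spatial kernel, analyzing each dataset with
the base model and the matched spatial model, and summarizes the gain in
accuracy (correlation between true and estimated genotypic effects).
A larger version of the same experiment (829 genotypes, phi up to 60.5)
is what scripts/acceptance.py runs.
"""

import gsspatial as gs

layout = gs.default_layout(n_genotypes=60, n_checks=4, check_reps=2, n_cols=10)
table = gs.run_grid(
    h_grid=[0.3],
    fra_grid=[0.5, 0.9],
    kernel_grid=[("gaussian", 8.0)],
    n_seeds=10,
    master_seed=2024,
    layout=layout,
)

for fra, grp in table.groupby("fra_sp"):
    base = grp[grp["model"] == "Base"].set_index("seed")["cor_g"]
    spatial = grp[grp["model"] != "Base"].set_index("seed")["cor_g"]
    gain = (100.0 * (spatial - base) / (1.0 - base)).mean()
    print(f"fra_sp={fra}: COR base {base.mean():.3f} -> "
          f"spatial {spatial.mean():.3f}  (relative gain {gain:.1f}%)")
# The accuracy gain from modeling the spatial field grows with the share
# of error variance that is spatial: correcting a strong smooth field
# returns much of the otherwise-confounded genotypic signal.
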