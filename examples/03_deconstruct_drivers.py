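"""Resolve whether a score association is polygenic or driver-dominated.

Runs the per-variant scan and greedy leave-variant-out loop on two
cohorts: one whose score association comes from a single upweighted
driver, one whose identical-strength association is spread across all
variants.
"""

import polyglia as pg
from polyglia.screen import COVARIATES_NEUROPATH


def deconstruct(spec, label):
    gm = pg.simulate_genotypes(spec, 1000)
    cov = pg.simulate_covariates(1000, seed=spec.seed)
    pheno, _ = pg.simulate_phenotypes(gm, spec, cov)
    rep = pg.find_drivers(
        pg.weight_table(spec, label), gm, pheno["microglia_all"], cov, COVARIATES_NEUROPATH
    )
    b = rep.baseline
    print(f"{label}: baseline t_{b['df']} = {b['t']:.2f}, p = {b['p']:.2g}")
    for step in rep.trace:
        print(f"  removed {step['removed']}: p -> {step['p']:.2g}")
    print(f"  verdict: {rep.verdict} (drivers: {rep.drivers})\n")
    return rep


rep1 = deconstruct(pg.ArchitectureSpec.single_driver(67, seed=31), "driver-architecture")
rep2 = deconstruct(pg.ArchitectureSpec.diffuse(67, seed=32), "diffuse-architecture")
# The first score collapses to null (p >= 0.05) after removing exactly
# its planted driver; the second survives five removals essentially
# unchanged - the two verdicts the deconstruction is designed to
# distinguish.
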