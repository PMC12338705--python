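"""Partition lifespan variance into genetic, environmental and G×E parts.

Simulates a small inbred-line panel measured in 6 environments (2 sexes x
3 temperatures), fits the four nested kernel mixed models by REML and
prints the proportion of variance explained (PVE) by each component. In
the full interaction model the PVE estimates should track the generating
fractions (0.12 genetic, 0.72 environment, 0.08 G×E, 0.08 residual).
"""

from gxepred import ModelSpec, SimulationConfig, fit_reml, partition_variance, simulate_dataset

cfg = SimulationConfig(n_lines=100, n_variants=1500, seed=7)
geno, pheno, truth = simulate_dataset(cfg)
ks = truth.kernels
y = pheno["lifespan"].to_numpy()

print(f"{cfg.n_lines} lines x 6 environments = {len(pheno)} records\n")
print(f"{'model':<10} {'genetic':>8} {'environ':>8} {'GxE':>8} {'residual':>9}")
for name in ("G-BLUP", "E-BLUP", "GE-BLUP", "GxE-BLUP"):
    spec = ModelSpec(name)
    fit = fit_reml(y, [ks.by_name(k) for k in spec.kernel_names], spec)
    pve = partition_variance(fit).pve
    cols = [pve.get("ZGZt", 0.0), pve.get("E", 0.0), pve.get("GxE", 0.0), pve["residual"]]
    print(f"{name:<10} " + " ".join(f"{v:>8.3f}" for v in cols[:3]) + f" {cols[3]:>9.3f}")

print(
    "\nWithout the environment kernel (G-BLUP) the genetic signal drowns in the\n"
    "unmodelled environmental variance; once E is in the model, genetics and\n"
    "the G×E interaction each recover their generating share."
)
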