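# carrierscreen

Most drugs enter cells through protein carriers rather than by passive
diffusion through the lipid bilayer. `carrierscreen` implements the
analysis side of a yeast chemical-genomics screen that identifies which
plasma-membrane transporter imports which drug: if a drug needs carrier X
to get in, the *xΔ* deletion strain is resistant, and that resistance can
be read out three ways — enrichment of the deletant in a drug-treated
competition pool, oversized colonies on a drug agar plate, and restored
growth curves in liquid culture. The package is aimed at computational
biologists analysing (or simulating) such screens.

## What it computes

* **Colony-array quantification** (`carrierscreen.colony`) — plate
  photographs are partitioned into diamond-shaped windows between four
  manually identified grid corners (window size =
  max(width/n_cols, length/n_rows)); the colony size is the number of
  blue-channel pixels above 1.25 × the window minimum.
* **Hit calling** (`carrierscreen.hits`) — border WT buffer excluded;
  per-strain score = 100 · median(drug spots) / median(control spots);
  z-scored against the plate; resistant if z > 3 (2.5/2 fallbacks),
  sensitive if z < −2.5.
* **Pool enrichment** (`carrierscreen.pool`) — per-strain barcode
  abundances (AFU) in treated vs untreated pools, total-sum normalized;
  enriched iff the difference clears a ±1000 AFU noise band (98% coverage
  of untreated replicates) **and** the treated/untreated ratio ≥ 3.
* **Growth analysis** (`carrierscreen.growth`) — μmax as the steepest
  sliding-window slope of ln(OD600); dose–response with SEM over
  replicates; Hill fit μ(c) = μ₀ / (1 + (c/IC50)^h) with closed-form IC90
  = IC50 · 9^(1/h); protection by a competing native substrate via
  c_eff = c / (1 + [competitor]/Ks) and the recovered rate fraction.
* **Evidence aggregation** (`carrierscreen.report`) — per-drug records
  (pool hits, robot hits with SD qualifiers, indirect genes, verification,
  protection, rule-of-five) and headline counts; a checksum-guarded
  26-drug summary fixture ships with the package.
* **Synthetic data** (`carrierscreen.simulate`) — seeded generators for
  every input: 384-well master / 768-spot test layouts for 111 transporter
  deletants with a WT border, rendered plate images with planted
  resistance, edge effects and suppressor colonies, exponential pool
  competitions with log-normal AFU readout, and lagged logistic growth
  curves under Hill inhibition.

## Worked example

Simulate a canavanine-like screen — one planted resistant deletant
(*can1Δ*, the arginine-permease mutant) among 111 transporter deletants,
90% growth inhibition for everyone else — and run all three platforms:

```python
from carrierscreen.pipeline import RunConfig, run_robot_screen, run_pool_screen, run_validation

cfg = RunConfig(rng_seed=42, drug="canavanine", conc_uM=5.0,
                resistant_strains=["can1Δ"])

robot = run_robot_screen(cfg)
print(robot.resistant_strains)     # ['can1Δ', 'tpn1Δ']
pool = run_pool_screen(cfg)
print(pool.calls.iloc[0][["strain_id", "rank_on_treated", "enriched"]])
val = run_validation(cfg)
print(val.ic_estimate)
```

At this seed the robot screen calls the planted *can1Δ* resistant
(score 93.7 vs a plate average near zero, z = 5.51) plus one false
positive, *tpn1Δ* — one suppressor colony was planted on this plate, and
suppressors are exactly the false-positive mode that makes agar screens
need liquid-culture validation. The pool screen ranks *can1Δ* first on the
treated axis (treated/untreated ratio 127.6, enriched). The validation run
estimates IC90 = 30.02 μM from simulated dose–response curves (true value
30 μM: IC50 10 μM, h = 2), and the protection sweep shows 10 μM of a
competing native substrate recovering 80% of the untreated growth rate
with the drug held at its IC90 — full protection as the competitor
saturates the shared carrier.

The same runs are available from the shell:

```sh
carrierscreen table1 --check        # fixture ok: 26 drugs, 18 with a direct hit, 14 Lipinski-pass
carrierscreen robot-screen --config run.yaml
carrierscreen pool-screen  --config run.yaml
carrierscreen validation   --config run.yaml
```

with subcommands `simulate`, `quantify`, `call-hits`, `pool-enrich`,
`growth`, `ic`, `protect`, `summarize`, `table1` for the individual
stages. Every output TSV starts with a metadata header (tool version, rng
seed, thresholds, config hash).

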