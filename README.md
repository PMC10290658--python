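# hybridsheet

Analysis toolkit for the enzyme–substrate **hybrid β-sheet** of
intramembrane aspartyl proteases (γ-secretase/presenilin-1 and its
APP/Aβ substrates): per-frame active-site feature extraction from
structures and trajectories, a Hamiltonian-replica-exchange
umbrella-sampling (HREUS) engine with WHAM free-energy estimation and
the ΔΔG_res extraction rule, and feature-vs-reaction-coordinate
profiling — validated end to end on synthetic fixtures and 1-D toy
potentials with analytically known free-energy profiles.

## Who this is for

Computational structural biologists studying how the substrate β3
strand (the P1′–P4′ residues downstream of the scissile bond) docks
onto the presenilin β1/β2 strands, closes the K380–L432 water gateway,
and stabilises a cleavage-compatible active-site geometry. The package
does **not** run all-atom MD; it implements the *analysis* layer and a
toy sampling stack whose statistical machinery (umbrella windows,
replica exchange, WHAM) is exactly testable.

## The quantities at the core

* **Active geometry**: a frame is cleavage-compatible iff
  `d1 < 2.5 Å` and `d2 < 5.6 Å`, where `d1` is the hydrogen bond from
  the protonated catalytic aspartate (D257^H or D385^H) to the scissile
  carbonyl O, and `d2` the distance from the deprotonated aspartate Cγ
  to the scissile carbonyl C.
* **β3 statistic**: `β3 = [β(P2′) + β(P3′)]/2`, the mean β-strand
  (DSSP E) occupancy of the P2′/P3′ register positions; substrates too
  short to have a P3′ residue use the single available occupancy.
* **Catalytic hydration**: number of water molecules with any atom
  within 5 Å of either catalytic aspartate, and per-water residence
  times (maximal runs of consecutive shell-resident frames).
* **Gap width**: Cα–Cα distance between K380 (β2) and L432 — the water
  gateway the β3 strand zips shut (≈11 Å closed).
* **HREUS/WHAM**: umbrella windows on the reaction coordinate
  RC = Cα(L418)–Cα(P2′), 8.0–17.0 Å at 0.6 Å (16 windows, window
  force constants 6/8/10 kcal mol⁻¹ Å⁻², bias `k·(x−c)²`), nearest-
  neighbour Hamiltonian swaps accepted with
  `min[1, exp(−Δ)]`, `Δ = β[(Hⁱ(r_j)+Hʲ(r_i)) − (Hʲ(r_j)+Hⁱ(r_i))]`;
  WHAM self-consistent PMF with
  **ΔΔG_res = PMF(16 Å) − PMF(min)** if the global minimum lies at
  RC < 11 Å, else 0.

## Worked example

```python
import numpy as np
from hybridsheet import (
    make_dissociation_trajectory, fixture_catalytic_spec, extract_features,
    make_toy_rc_potential, protocol_windows, metropolis_sample, wham, ddg_res,
)

# a planted β3-dissociation event at frame 50 of 100 (1 ns/frame)
traj, truth = make_dissociation_trajectory(100, 50, seed=5)
fs = extract_features(traj, fixture_catalytic_spec())
print(f"active fraction {fs.active_fraction:.2f}  beta3 {fs.beta3:.2f}  "
      f"mean waters {fs.water_counts.mean():.1f}")

# recover a planted association free-energy difference of 3 kcal/mol
pot = make_toy_rc_potential(ddg_target=3.0)
wins = protocol_windows()
samples = [metropolis_sample(pot, w, 100_000, seed=i, burn_in=2000)
           for i, w in enumerate(wins)]
res = ddg_res(wham(samples, wins))
print(f"ddg_res {res.ddg_res:.2f} kcal/mol  (min at {res.min_location:.2f} A, "
      f"branch {res.rule_branch})")
```

prints

```
active fraction 0.49  beta3 0.50  mean waters 3.5
ddg_res 3.01 kcal/mol  (min at 8.95 A, branch associated-min)
```

The active fraction and β3 sit at 0.5 because half the frames precede
the planted dissociation; the mean water count mixes the one resident
water of the closed state with the six that flood in once the gate
opens. The recovered ΔΔG_res is within sampling error of the planted
3 kcal/mol.

A CLI mirrors the library (`hybridsheet fixtures|features|hreus-wham|
survey|profile|decompose`, each with `--seed`, `--config`, `--out`).

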