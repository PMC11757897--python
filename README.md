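# hemonet

Steady-state blood flow with haematocrit transport in small microvascular
networks, and the bifurcation structure of its equilibria.

## The problem

Microvascular blood flow is usually modelled as Poiseuille flow on a graph:
vessels are rigid tubes, junction pressures drive flows through hydraulic
resistances, and red blood cells (RBCs) are carried with the flow.  Two
empirical effects make the problem nonlinear and interesting:

* the **Fåhræus–Lindqvist effect** — the apparent viscosity µ(H, D) of blood
  depends on the tube haematocrit H and strongly on the vessel diameter D
  (µm), via the in-vivo law of Pries and co-workers,
* **plasma skimming** — at a diverging junction the RBC flux splits
  disproportionately between the daughters: the daughter receiving the flow
  fraction r = Q_daughter/Q_parent receives the RBC fraction

      ψ(r) = 0                     for r < X0,
             1                     for r > 1 − X0,
             e^A (r−X0)^ρ / (e^A (r−X0)^ρ + (1−r−X0)^ρ)   otherwise,

  with A = −(6.96/D_p) ln(D_d/D_s), ρ = 1 + 6.98(1−H_p)/D_p, X0 = 0.4/D_p
  (the Pries-1990 rule; other rules plug into the same interface).

Because viscosity depends on haematocrit and haematocrit depends on how the
flow splits, the steady state is the root of a nonlinear system
F(H, P) = 0: one flow-conservation equation per interior node and one RBC
equation per non-inlet vessel (plain RBC conservation at converging
junctions, the ψ condition at diverging ones).  Networks that contain
**redundant vessels** — vessels whose flow direction is not fixed by the
geometry, equivalently vessels that sit on a loop — can support *multiple*
coexisting equilibria, at most 3^r of them for r redundant vessels, one per
combination of negative / intermediate / positive cross-vessel flow.  That
multiplicity is a candidate mechanism for heterogeneous and fluctuating
perfusion (and hence cycling hypoxia) in tumour microvasculature.

The package ships the two canonical study networks: the **triangle** (two
inlets, one outlet, one redundant vessel, 3 equilibria) and the
**extended-triangle** (one extra cross vessel, two redundant vessels, 9
equilibria), parameterised by the length ratios α (cross vessels) and β
(asymmetry), a common diameter D, boundary pressures and the inlet
haematocrit.

## What it does

* `hemonet.topology` — networks as graphs; exhaustive enumeration of
  feasible acyclic flow orientations; redundant-vessel detection.
* `hemonet.rheology` — the in-vivo viscosity law and hydraulic resistance.
* `hemonet.splitting` — the Pries-1990 splitting rule behind a pluggable
  rule registry.
* `hemonet.steady_state` — assembly of the dimensionless network equations
  (flows normalised by total inflow), finite-difference Jacobians, damped
  Newton.
* `hemonet.continuation` — homotopy for a first equilibrium,
  pseudo-arclength branch tracing with fold detection/refinement,
  equilibrium enumeration (multistart + continuation seeding), flow-state
  labelling.
* `hemonet.experiments` — β/α/H_in/pressure sweeps, (α, β) region maps,
  critical-haematocrit curves over diameter.
* `hemonet.fixtures` — the two canonical networks plus seeded random small
  networks for property tests.
* `hemonet.netio` / `hemonet.cli` — JSON network format, CSV writers and
  the `hemonet` command-line tool.

## Worked example

```python
from hemonet import (build_triangle, compile_network,
                     enumerate_equilibria, classify_flow_state)

net = build_triangle()                      # alpha=0.1, beta=1, D=10, H_in=0.45
sysm = compile_network(net)
eq = enumerate_equilibria(sysm, n_starts=200, seed=1)
for st, label in zip(eq, classify_flow_state(eq)):
    print(label, f"Q<4,5> = {st.flow(4, 5):+.5f}",
          f"H(4,6) = {st.haematocrit(4, 6):.4f}",
          f"H(5,6) = {st.haematocrit(5, 6):.4f}")
```

prints

```
('-',) Q<4,5> = -0.05767 H(4,6) = 0.4173 H(5,6) = 0.4914
('0',) Q<4,5> = +0.00000 H(4,6) = 0.4500 H(5,6) = 0.4500
('+',) Q<4,5> = +0.05767 H(4,6) = 0.4914 H(5,6) = 0.4173
```

three coexisting equilibria distinguished by the flow state in the redundant
vessel ⟨4,5⟩ (negative / intermediate / positive).  The (+) state pushes
extra red cells down the left outlet branch (H = 0.491 > 0.45) and starves
the right one — an asymmetric haematocrit distribution in a perfectly
symmetric network.  Tracing these equilibria in the asymmetry ratio β,

```python
from hemonet.experiments import beta_sweep
res = beta_sweep(net, (0.5, 1.5), seeds=eq, seed=1)
print(sorted(res.fold_lams))   # [0.9629..., 1.0385...]
```

shows the S-shaped branch structure: the three states merge pairwise at two
fold bifurcations near β ≈ 0.96 and β ≈ 1.04, outside of which the
equilibrium is unique.  The same drivers reproduce the extended-triangle
diagrams (8 folds), the inlet-haematocrit sweep (first extra pair emerging
near H_in ≈ 0.32 at D = 10) and the critical curve H^(3)(D), which peaks
near D ≈ 50 µm.

The same analyses are available from the shell:

```sh
hemonet equilibria --fixture extended-triangle
hemonet sweep-beta --fixture triangle --range 0.5 1.5 --out sweep.csv
hemonet regions-dh --n-d 20 --out h3_curve.csv
```

## Limitations

Interior junctions are restricted to degree 3 (the splitting rule is a
two-daughter rule); stability of the equilibria and time-dependent dynamics
(oscillations, stochastic switching) are out of scope.  See
`docs/methods.md` for the model, numerics and known discrepancies.
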