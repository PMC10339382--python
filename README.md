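# toothmor

Real-time parametric stress surrogates for transplanted-tooth biomechanics.

Finite-element analysis of a tooth anchored in bone is too slow for
interactive use: every occlusal load case is a fresh nonlinear solve.
`toothmor` implements the offline/online model-order-reduction workflow
that removes the solver from the loop. Offline, a plane-strain
finite-element model of a tooth cross-section — linear-elastic dentin and
bone around a first-order Ogden hyperelastic periodontal ligament — is
solved on a uniform grid of occlusal forces (lateral Fy, axial Fz, each
50–200 N) and the nodal von Mises stress (VMS) snapshots are compressed
into a separated tensor representation

    S(x, Fy, Fz) ≈ Σₘ aₘ(x) · gₘ(Fy) · hₘ(Fz),

built by greedy rank-one enrichment with alternating fixed-point
iterations. Online, a new force pair inside the grid is answered in
milliseconds by interpolating the parametric mode functions gₘ, hₘ — no
finite-element solve. Accuracy is certified by the relative L2 error

    δ = ‖U − U_ref‖₂ / ‖U_ref‖₂

at the centers of the parameter-grid subdomains, the points farthest from
the training data. The package is aimed at researchers in computational
biomechanics who want a small, fully inspectable reference implementation
of this workflow — mesh generator, nonlinear solver, decomposition, error
certification and trend analysis included, with exact separable oracles
for every stage.

## Worked example

`examples/03_reduce_and_query.py` runs the whole loop on a coarse section
(9 offline solves on a 3×3 grid, then one online query):

```
offline: 9 FE solves in 15.5 s -> 35 modes, residual 8.65e-07
online query at (110, 140) N: 4.17 ms, max VMS 7.152 MPa
relative L2 error vs fresh FE solve: 3.10 %
```

The offline stage costs seconds per snapshot; the online query costs
milliseconds and errs by a few percent at the worst-case (cell-center)
locations — the error shrinks as the training grid is refined. A single
load case looks like this (`examples/02_single_solve.py`):

```
Newton iterations: 17 over 4 load increments
reaction resultant (N/mm depth): [-1.666667  3.333333]
applied resultant  (N/mm depth): [ 1.666667 -3.333333]
max von Mises in DENTIN:    3.607 MPa
max von Mises in PDL   :    1.537 MPa
max von Mises in BONE  :    1.251 MPa
```

Reactions balance the applied resultant exactly; the stiff dentin carries
the highest equivalent stress while the compliant ligament cushions the
root. The other examples build the mesh (`01`), tabulate the per-center
error report (`04`), and extract extreme-VMS response surfaces with their
linear/quadratic force trends per tissue (`05`).

A thin CLI wraps the same library calls:

```bash
toothmor run --config config.yaml          # full workflow
toothmor predict 110 140 --out toothmor_out  # real-time query
```

with subcommands `mesh`, `snapshots`, `reduce`, `errors`, `surface`,
`predict`, `run`. See `docs/methods.md` for the model, parameter defaults
and numerical choices.

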