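# pnpiv — current–voltage relations for quasi-1D PNP ion-channel models

`pnpiv` is a small scientific library and CLI for membrane biophysicists and
applied mathematicians studying ionic flow through a single open channel
with the steady-state Poisson–Nernst–Planck (PNP) model. It targets the
regime of a **small permanent charge** `Q0` confined to the channel neck and
**relaxed electroneutrality boundary conditions**, where thin boundary
layers at the channel ends reshape the current–voltage (I–V) relation.

For two species with valences `z1 > 0 > z2`, diffusivities `D1, D2`,
boundary concentrations `L1, R1` and neutrality-relaxation factors
`(sigma, rho)` (`sigma = rho = 1` is exact neutrality), the current expands
as

```
I(V; Q0) = I0(V) + I1(V) Q0 + o(Q0),
I0 = P00 + P01 V,        I1 = P10 + P11 V + P12 V^2,
```

with closed-form coefficients built from the resistance integral
`H(x) = ∫ dx/h(x)` of the cross-section profile and the window positions
`alpha = H(a)/H(1)`, `beta = H(b)/H(1)` of the permanent charge. The
package provides:

- the exact P-coefficients and fluxes, assembled along two independent code
  paths that are cross-checked against each other (`pnpiv.iv`, `pnpiv.flux`);
- the first-order expansion about electroneutrality, the boundary-layer
  difference terms `I0d`, `I1d`, and a finite-difference integrity oracle
  for every closed-form derivative (`pnpiv.expansion`);
- the sign/threshold analysis — `t*`, `alpha1`, `alpha3`, `alpha4`,
  `alpha*`, `beta1`, the discriminant `Delta` — and all critical potentials
  (`pnpiv.sign_analysis`);
- a collocation solver for the full singularly perturbed system at finite
  `eps`, with interface conditions at the charge jumps, continuation in
  `eps`, numeric I–V curves and numeric critical potentials (`pnpiv.bvp`);
- a CLI (`pnpiv analytic | expansion | critical | bvp | verify | preset`)
  over TOML/JSON configs (`pnpiv.cli`, `pnpiv.presets`).

## Worked example

The default configuration is the reference study setup: `z1 = -z2 = 1`,
`D1 = 2.032`, `D2 = 1.334`, `L1 = 12`, `R1 = 8`, `Q0 = 0.008`,
`eps = 0.01`, neck on `(0.4, 0.48)` with `r0 = 0.5`, and relaxation
`(sigma, rho) = (1.2, 0.9)`.

```
$ pnpiv critical
$ python -m json.tool pnpiv-out/critical.json
...
"critical": {
    "V0d": 3.8718964774420983,
    "V0d_label": "V01d",
    "V1c": 1.051146560308788,
    "V1d_pair": null,
    "Delta": -0.0004103392187539664,
    "V01EN": -0.08408040566235855,
    "V01bd": 0.029932631964104825,
    ...
}
```

Reading this: the boundary-layer correction to the zeroth-order current,
`I0d(V)`, is increasing in `V` and crosses zero at `V01d ≈ 3.87` — layers
*enhance* the current above that potential and *reduce* it below.
The zeroth-order reversal potential sits at `V01EN ≈ -0.084` (units kT/e)
under neutral boundaries and moves to `V01bd ≈ +0.030` when the layers are
present: for `-0.084 < V < 0.030` the two setups predict currents of
opposite sign, which is exactly why boundary layers matter. For this
channel geometry the first-order term `I1d` has negative discriminant
(`Delta ≈ -4.1e-4`, `V1d_pair: null`): it never changes sign, and its
extremum lies at `V1c ≈ 1.05`.

The analytic and numeric I–V tables come from

```
$ pnpiv analytic        # closed forms ->  pnpiv-out/iv_analytic.csv
$ pnpiv bvp             # collocation  ->  pnpiv-out/iv_numeric.csv
$ head -2 pnpiv-out/iv_analytic.csv
V,I0,I1,I
-1,-49.430933256868798,-0.12533058026261829,-49.431935901510897
```

and `pnpiv verify` runs the formula-integrity oracles (ten closed-form
derivatives vs finite differences, Taylor-remainder order), exiting nonzero
on any failure.

As a library:

```python
from pnpiv import (SpeciesPair, BoundaryState, cylindrical_channel,
                   p_coefficients)
sp = SpeciesPair(1, -1, 2.032, 1.334)
geom = cylindrical_channel(0.4, 0.48, 0.5, Q0=0.008)
pc = p_coefficients(sp, BoundaryState(V=0.0, L1=12, R1=8), geom)
print(pc.I0(0.0))        # 3.9359836443860674  (current at V = 0, Q0 = 0)
print(-pc.P00 / pc.P01)  # -0.08408040566235855  (reversal potential)
```

See `docs/methods.md` for the model, assumptions, numerical choices and
known limitations.

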