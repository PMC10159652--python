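# exprflux

Expression-weighted parsimonious flux balance analysis (FBA) for
multi-tissue, diel plant metabolic models.

## The problem

Parsimonious FBA (pFBA) predicts a steady-state flux map by minimizing
total flux through a stoichiometric network, but in a multi-tissue model
(e.g. leaf / stem / root, each duplicated for day and night) many
alternative route choices have identical total flux, and pFBA has no way
to decide which tissue actually runs which pathway. Tissue-atlas
transcriptomes and proteomes carry exactly that missing information: a
reaction whose enzyme genes are highly expressed in the leaf and barely
expressed in the root is more likely to carry flux in the leaf.

`exprflux` turns inter-tissue relative abundances into per-reaction
penalty weights and solves

```
min  Σ_j c_j |v_j|      s.t.  S v = 0,  LB_j ≤ v_j ≤ UB_j,
                              v_biomass(tissue) = fixed value
```

with the penalty weight of reaction *R* in tissue *t* built from its
gene–protein–reaction (GPR) rule:

```
W_it = max(E_i) / E_it                       (per-gene weight, ≥ 1)
w_R  = GPR-fold(W):  OR → mean, AND → max    (isozymes vs complex subunits)
c_R  = SF · (w_R − 1) + 1                    (scaling factor SF ≥ 0)
```

Only *relative* abundance across tissues matters, so TPM-like transcript
values and IBAQ-like protein intensities are both valid inputs. At
SF = 0 every c_j is 1 and the method reduces exactly to pFBA.

Predicted maps are scored against 13C-MFA flux estimates: model fluxes
are rescaled once by A = (measured net CO₂ uptake)/(model net CO₂
uptake), and agreement is summarized as the weighted-average percent
error `100 · Σ|A·v_p − v_m| / Σ|v_m|`, bracketed by min/max values
derived from flux variability analysis (FVA) over the near-optimal face.

## Worked example

The package ships a synthetic-data generator that builds a small
three-tissue diel plant with parallel pathway routes whose true usage is
planted in an expression table, plus an MFA comparison derived from the
planted flux map:

```python
import exprflux as xf

bundle = xf.make_toy_plant(seed=1)
model, expr, mfa = bundle.model, bundle.expression, bundle.mfa

def score(weights):
    sol = xf.minimize_weighted_flux(model, weights)
    A = xf.normalization_factor(sol, mfa)
    return sol, xf.weighted_average_error(sol, mfa, A)

pfba_sol, pfba_err = score(None)                      # all c_j = 1
wv = xf.build_weight_vector(model, expr, sf=1.0)      # expression weights
w_sol, w_err = score(wv)

print(f"reactions: {len(model.reactions)}   MFA-paired fluxes: {len(mfa.entries)}")
print(f"pFBA       error: {pfba_err:6.2f} %   objective: {pfba_sol.objective:.4f}")
print(f"weighted   error: {w_err:6.2f} %   objective: {w_sol.objective:.4f}")

subset = sorted({r for e in mfa.entries for r, _ in e.combo})
fva = xf.run_fva(model, wv, reactions=subset, incumbent=w_sol)
lo, hi = xf.error_bounds(fva, mfa, xf.normalization_factor(w_sol, mfa))
print(f"FVA error bounds around the weighted map: [{lo:.2f} %, {hi:.2f} %]")
```

prints

```
reactions: 131   MFA-paired fluxes: 40
pFBA       error:  28.57 %   objective: 0.7500
weighted   error:  14.29 %   objective: 0.7900
FVA error bounds around the weighted map: [0.00 %, 14.29 %]
```

pFBA takes the stoichiometrically cheapest route everywhere and is
systematically wrong in the tissue that really runs the longer,
complex-catalysed pathway; the expression weights pay a slightly higher
flux objective (0.79 vs 0.75) to follow the tissue signal and halve the
error. The residual 14.29 % is the irreducible cost of reporting a
single LP vertex for isozyme pairs whose true flux is split 50/50 — the
FVA lower bound of 0 % shows the true map lies inside the optimal face.

A command-line interface covers the same pipeline stage by stage
(`exprflux fixture / build / weights / solve / fva / evaluate / sweep`);
`exprflux evaluate --controls permute:n=20,seed=7` adds the
permuted-weight negative control, and `exprflux sweep` tabulates error
against the scaling factor.

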