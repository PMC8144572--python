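# flexsas

Small-angle scattering (SAXS/SANS) modelling and inference for flexible,
detergent-solubilized membrane receptor complexes — the kind of analysis used
to decide whether a photoreceptor/transducer complex such as NpSRII/NpHtrII
is a flexible dimer or a "tripod"-shaped trimer of dimers in solution.

## What it does

Solution scattering measures the orientation-averaged intensity

> I(q) = Σᵢ Σⱼ Δbᵢ Δbⱼ sin(q rᵢⱼ)/(q rᵢⱼ),  Δbᵢ = bᵢ − ρₛVᵢ

of a particle's point scatterers (the Debye formula). On top of this forward
model the package provides the full inference chain:

- **Model geometry** — bead/atom `ParticleModel`s read from PDB or generated
  synthetically; membrane-frame orientation, rigid hinge bending of the
  ~200 Å cytoplasmic rod at the HAMP1/HAMP2/Gly hinges, exact-C3 assembly of
  trimers of dimers (tripod or TM-bound), Rg and inter-dimer distances.
- **Detergent corona** — a two-shell DDM belt of pseudo-atoms around the
  transmembrane part: a 9-electron CH3-like tail pseudo-atom carrying 9/97 of
  the C12H25 tail scattering and a 10-electron head pseudo-atom carrying
  10/181 of the C12H21O11 maltoside head, with the head's seven exchangeable
  hydrogens deuterated according to the solvent D2O fraction. Reproduces the
  belt neutron scattering lengths (−1.27 fm, 7.62 fm), the equivalent CH3
  perdeuteration parameters (0.1056, 0.3904) and the shell SLDs
  (−0.388×10⁻⁶, 3.92×10⁻⁶ Å⁻²).
- **Forward scattering** — X-ray/neutron Debye curves with solvent-contrast
  bookkeeping (NaCl molarity, D2O fraction), histogram-accelerated pair sums,
  and reduced-χ² model/data comparison.
- **Model-free curve analysis** — Guinier fits, Tikhonov-regularized indirect
  Fourier transform to P(r) with non-negativity and pinned endpoints, P(r)
  moments and peaks, dimensionless Kratky plots.
- **Ensemble & mixture inference** — (1) fit a curve as a regularized
  non-negative combination of 343 hinge-bent conformer curves (−90°…90° in
  30° steps on three hinges) and report per-hinge RMS bending angles;
  (2) fit dimer vs trimer-of-dimers weight fractions with 1σ uncertainties
  and rank competing trimer hypotheses by χ².
- **Synthetic data** — toy receptor dimers, heteroscedastic SANS-like noise
  (σ/I ≈ 2–15 %), hinge-angle ensembles and two-component mixtures with
  exact ground truth, so every stage is testable end to end.

## Worked example

Recover a known trimer-of-dimers fraction from a synthetic SANS mixture:

```python
import numpy as np, flexsas as fx
from flexsas.synthetic import NoiseSpec, make_mixture_dataset

dimer, segmap = fx.make_toy_dimer()
trimer = fx.assemble_c3(dimer, 52.0, mode="tripod")   # TM centroids 90 Å apart
solvent = fx.solvent_model(4.0, 1.0)                  # 4 M NaCl in D2O
q = np.geomspace(0.007, 0.25, 101)

dimer_curve, trimer_curve = fx.component_curves(dimer, trimer, solvent, q, "neutron")
data, truth = make_mixture_dataset(dimer_curve, trimer_curve, 0.36,
                                   NoiseSpec(seed=111), seed=11)

res = fx.mixture_fractions([dimer_curve, trimer_curve], data)
print(f"trimer fraction: {res.fractions[1]:.1f} +/- {res.uncertainties[1]:.1f} %  (chi2 = {res.chi2:.2f})")

pr = fx.ift_pr(data, dmax=320.0)
print("P(r) peaks at r =", [round(p, 1) for p in fx.pr_peaks(pr)], "A")
```

prints

```
trimer fraction: 35.6 +/- 0.6 %  (chi2 = 0.85)
P(r) peaks at r = [19.2, 92.8, 297.6] A
```

The generated mixture contained 36 % trimer; the fit recovers it within its
1σ uncertainty. The P(r) shows the two physical distance populations — the
short intra-dimer peak and the ~93 Å inter-dimer peak characteristic of the
tripod arrangement (the weak feature near Dmax is a truncation artifact of
the noisy low-q data).

A command-line surface wraps the same functions:

```sh
flexsas simulate --out sim.dat --seed 3     # synthetic noisy curve + truth JSON
flexsas guinier sim.dat                     # Rg, I(0)
flexsas pr sim.dat --dmax 260 --out pr.out  # regularized P(r)
flexsas fit-ensemble --data sim.dat         # hinge-ensemble weights, RMS angles
flexsas fit-mixture --data m.dat --components dimer.dat trimer.dat
flexsas run config.yaml                     # full pipeline from a YAML config
```

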