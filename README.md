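# sarm1tk

Quantitative toolkit for studies of SARM1, the NAD-cleaving enzyme (NADase)
that executes programmed axon death. SARM1 is controlled allosterically
through its armadillo-repeat (ARM) domain, where pyridine mononucleotides —
the endogenous activator NMN and, far more potently, the vacor metabolite
VMN — bind and switch catalysis on. The package is for enzymologists and
structural biologists who need to turn raw assay readouts into kinetic and
thermodynamic constants:

- **Dual-effector kinetics** — evaluate and fit a Michaelis–Menten rate law
  extended for a single reversible effector I acting through distinct
  activation and inhibition sites:

  V = Vmax · (X + (1−X)/(1+([I]/Kₐ)ⁿ)) · (Y + (1−Y)/(1+([I]/Kᵢ)ⁿ)) · [S]/(Kₘ+[S])

  X is the fold activation at saturating effector, Y the residual activity
  fraction, Kₐ/Kᵢ the site affinities and n the Hill cooperativity. X > 1
  with Y < 1 and Kₐ < Kᵢ produces the biphasic (bell-shaped) dose-response
  characteristic of VMN.
- **Assay rates** — initial rates from discontinuous NAD-consumption time
  courses (linear window at ≤ 20% substrate consumption, ADPR + cADPR as
  the consumption proxy), specific activities in milliU/mg, fold changes
  and relative percentages.
- **ITC binding** — simulate and fit one-site isotherms under an
  overflow-cell dilution model (n, K_d, ΔH, offset), with the Wiseman
  c-value as identifiability diagnostic.
- **Structure comparison** — Cα pairing, Kabsch SVD superposition with
  iterative outlier rejection, RMSD reporting, and N/O polar-contact
  enumeration for ligand pockets (PDB/mmCIF via gemmi).
- **Synthetic data** — seeded generators for all three input types, with
  presets reproducing the study system's qualitative behaviours (biphasic
  VMN, monotone NMN, non-responding K193R pocket mutant).

## Worked example

Fit the dual-effector model to a simulated triplicate VMN-style
dose-response (5% CV noise) and locate the peak response:

```python
import sarm1tk as s

table = s.gen_dose_response("hSARM1_VMN", replicates=3, noise_cv=0.05, seed=42)
fit = s.fit_dual_effector(table, options={"seed": 0})
p = fit.params
print(p.x_act, p.y_res, p.ka, p.ki)
i_star, fold_star = s.peak_effector_response(p, (1e-3, 1e5))
```

Running `python examples/dose_response_fit.py` prints:

```
simulated 33 points (hSARM1_VMN, kind=fold)
X (fold activation at saturation) = 9.80
Y (residual fraction at saturation) = 0.147
Ka = 2.78 uM   Ki = 309.3 uM
Hill n_act = 2.37   n_inh = 1.96
RSS = 1.4135 over 33 points; flags: ['vmax not estimable from fold data (baseline fixed at 1)']
peak response: 9.69-fold at 24.8 uM effector
```

The generating parameters were X = 10, Y = 0.15, Kₐ = 3 µM, Kᵢ = 300 µM,
n = 2: the fit recovers the activation constant, the inhibition constant
and both asymptotes from noisy fold data, and the peak location says where
activation gives way to the inhibitory site. The other scripts under
`examples/` walk through rate extraction (`rate_extraction.py`), ITC
fitting (`itc_fit.py`) and structural superposition
(`superpose_structures.py`) the same way.

A thin CLI mirrors the library:

```sh
sarm1tk simulate-dose-response --preset hSARM1_VMN --seed 1 --out dose.csv
sarm1tk fit-kinetics --data dose.csv
sarm1tk superpose --mobile a.pdb --target b.pdb --range 373:444
```

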