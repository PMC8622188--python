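# dnapendulum

Sequence-dependent simulation of torsional base dynamics in double-stranded
DNA, for studying how the viscosity of the surrounding medium controls the
stability of base angular oscillations — the mechanical precursor of open
states and denaturation bubbles.

## The model

Each nitrogenous base is a pendulum rotating about the elastic
sugar-phosphate backbone; complementary bases are joined by an elastic
hydrogen-bond link. For a duplex of *n* base pairs the angles
φ<sub>ji</sub>(t) (strand *j*, site *i*, counterclockwise) obey 2*n* Newton
equations. Interior sites of strand 1:

    I₁ᵢ φ̈₁ᵢ = K₁ᵢ(φ₁,ᵢ₋₁ − 2φ₁ᵢ + φ₁,ᵢ₊₁)
              − k₁₂ᵢ R₁ᵢ(R₁ᵢ+R₂ᵢ) sin φ₁ᵢ
              − k₁₂ᵢ R₁ᵢR₂ᵢ sin(φ₁ᵢ − φ₂ᵢ) + F₁ᵢ(t)

with single-neighbour coupling at the chain ends, and strand 2 carrying its
published sign structure (`+k₁₂ᵢ R₂ᵢ(R₁ᵢ+R₂ᵢ) sin φ₂ᵢ`; a `symmetrized`
diagnostic variant mirrors strand 1 — see `docs/methods.md` for the
stability consequences). The external influence is

    Fⱼᵢ(t) = −λ βⱼᵢ φ̇ⱼᵢ + M(t),

viscous dissipation scaled by the dimensionless solvent-viscosity factor λ
plus an applied torque M(t) (constant, cosine, or zero; working value
10⁻²² N·m). Per-base coefficients I, R, K, k₁₂, β are tabulated for
A/T/G/C and mapped from the input sequence; the complementary strand is
derived automatically. Starting from equilibrium, the system is integrated
as a Cauchy problem with a fixed-step classical 4th-order Runge–Kutta
scheme (default dt = 10⁻¹⁴ s; adaptive SciPy backend optional).

The stability observable is the strand-averaged deviation
φ̄(t) = n⁻¹ Σᵢ φ₁ᵢ(t): its oscillation envelope is extracted and an
exponential decay rate fitted, so runs at different λ can be compared
quantitatively.

## Worked example

```python
import dnapendulum as dp

seq = dp.random_sequence(dp.SequenceSpec(n=100, seed=11))
sweep = dp.viscosity_sweep(seq, lambdas=(0.1, 0.5, 1.0, 2.0, 4.0), t_end=2e-9)
print(sweep.to_frame().to_string(index=False))
```

```
 lambda   decay_rate  early_amplitude  late_amplitude  amplitude_ratio  fit_quality
    0.1 3.130337e+08         1.831213    5.185253e-01     2.831595e-01     0.093738
    0.5 1.766863e+09         1.765515    8.099848e-02     4.587810e-02     0.703254
    1.0 3.288290e+09         1.848468    4.736772e-03     2.562539e-03     0.925345
    2.0 6.070987e+09         1.584132    7.658546e-05     4.834539e-05     0.978162
    4.0 1.173779e+10         1.821244    9.397563e-09     5.159969e-09     0.990157
```

Each row is one 2-ns simulation of the same 100-bp duplex under a constant
10⁻²² N·m torque, differing only in the viscosity scale λ. `decay_rate`
(1/s) is the exponential rate at which the mean-angular-deviation envelope
settles: it grows monotonically with λ. `amplitude_ratio` compares the
largest oscillation amplitude in the final sixth of the window with the
first sixth: at λ = 0.1 the molecule retains ~28% of its early amplitude
(essentially unattenuated vibration — an instability precursor), while at
λ = 1 the oscillation has decayed a thousandfold. The low `fit_quality`
(R² of the log-envelope fit) at λ = 0.1 reflects exactly that near-absence
of decay.

The same pipeline is available from the shell:

```bash
dnapendulum make-fixture --n 980 --gc 0.5 --seed 42 --out seq.fasta
dnapendulum simulate --fasta seq.fasta --lambda 1.0 --torque 1e-22 \
    --t-end 2e-9 --out run1
dnapendulum sweep --fasta seq.fasta --lambdas 0.1,0.5,1,2,4 \
    --t-end 2e-9 --out sweepdir
```

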