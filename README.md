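# gelstream

Simulation and analysis of **continuous-flow pulsed-field gel
electrophoresis** of DNA: the deflection-based separation of sub-10-kbp
fragments in an agarose-filled microchamber under two alternately applied,
roughly orthogonal electric fields of very different magnitude.

DNA in a sieving gel migrates by biased reptation, so its mobility μ
depends on both the field strength E and the contour length L, and after a
field switch a chain needs a reorientation time t_or = L/(μE) to realign
(reorientation frequency f_or = μE/2L). Alternating a strong field E₁ at
angle θ₁ with a weak field E₂ at θ₂ therefore sends each fragment length
down its own trajectory at angle

    Φ = atan2(v₁ sinθ₁ + v₂ sinθ₂, v₁ cosθ₁ + v₂ cosθ₂),
    vᵢ = max(μᵢEᵢ − 2fL, 0),

separating a mixture into parallel streams that can be collected
continuously — and separating DNA from small ions, which follow the
steeper mobility-free angle Φ₀. Separation quality is quantified the way
electropherograms are: Gaussian peak fits of the collection-line intensity
profile, resolution Rs = ΔX/(2σ₁+2σ₂), Gaussian-overlap purity
(overlap = 100·Q(2Rs) with Q the standard normal survival function), and
recovery (outlet/inlet integrated fluorescence).

The package is aimed at anyone designing or reasoning about such devices:
it provides the mobility/kinetics model (`gelstream.mobility`), the
deterministic migration-angle model and frequency sweeps
(`gelstream.deflection`), a stochastic sawtooth particle simulator with
synthetic fluorescence-image rendering (`gelstream.simulate`), the
image-to-report measurement chain (`gelstream.profiles`), and a CLI for
reproducible runs (`gelstream.cli`).

## Worked example

Five fragment lengths under the highest-resolution protocol (E₁ = 59.5,
E₂ = 22.4 V cm⁻¹, θ₁ = 25°, θ₂ = 115°, 2 Hz), using the packaged synthetic
calibration table:

```python
import gelstream as gs

model = gs.synthetic_mobility_model()
protocol = gs.FieldProtocol(59.5, 22.4, 25.0, 115.0, f_Hz=2.0)
for length in (500, 1000, 2000, 5000, 10000):
    frag = gs.FragmentSpec(length)
    res = gs.migration_angle(protocol, frag, model)
    print(f"{length:>6} bp  phi = {res.phi_deg:5.2f} deg  regime = {res.regime}")
print(f"ion angle = {gs.ion_angle(protocol):.2f} deg")
```

```
   500 bp  phi = 42.77 deg  regime = field_dependent_mobility
  1000 bp  phi = 40.27 deg  regime = field_dependent_mobility
  2000 bp  phi = 36.33 deg  regime = field_dependent_mobility
  5000 bp  phi = 25.86 deg  regime = field_dependent_mobility
 10000 bp  phi = 25.00 deg  regime = switchback_window
```

Five distinct streams: the shorter fragments deflect more (their
strong/weak mobility ratio is closer to 1), while the 10 kbp fragment is
already clamped to the strong-field direction — at 2 Hz it cannot reorient
in the weak field at all. Every DNA angle lies below the ion angle of
45.63°, which is why the device also purifies DNA from salts. At f → 0 the
5 and 10 kbp fragments co-migrate (equal mobility ratios) and only four
streams appear.

Purity bookkeeping from fitted resolutions:

```python
print(gs.purity_table([1.3, 0.6, 1.0, 1.4]).to_string(index=False))
```

```
  pair  Rs  overlap_pct  purity_pct
pair 1 1.3         0.47        99.5
pair 2 0.6        11.51        88.5
pair 3 1.0         2.28        97.7
pair 4 1.4         0.26        99.7
```

An Rs of 0.6 means 11.5% of each stream's Gaussian area falls past the
midpoint toward its neighbour (88.5% pure); Rs ≥ 1.3 is essentially
baseline separation.

The same workflows are scriptable from the shell — `gelstream angle-sweep`
(deflection spectra over a frequency grid), `gelstream simulate`
(stochastic streams, exit profiles, synthetic TIFF + ground-truth
sidecar), `gelstream analyze` (TIFF → profile → separation report) and
`gelstream purity-table`; every run writes a manifest with the fully
materialized config, seed and version.

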