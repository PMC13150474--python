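# spikesusc

Weakly nonlinear stimulus encoding in electroreceptor afferents: stochastic
leaky integrate-and-fire (LIF) models of P-units, band-limited noise and beat
stimuli, segment-averaged first- and second-order susceptibility estimation,
the susceptibility index SI(r), and the Furutsu–Novikov noise split.

## The scientific problem

P-units, the tuberous electroreceptor afferents of the weakly electric fish
*Apteronotus leptorhynchus*, encode amplitude modulations (AMs) of the fish's
self-generated electric organ discharge (EOD).  When two fish meet, the
superposition of their EODs produces a beat — a periodic AM at the difference
of the two EOD frequencies.  A spiking neuron is a nonlinear device: driven
with two beat frequencies f₁ and f₂ simultaneously, it can respond at the sum
f₁+f₂ and the difference f₂−f₁, frequencies that are absent from the
stimulus.  Theory for LIF-type neurons in the supra-threshold regime predicts
that these weakly nonlinear responses concentrate where f₁, f₂, or f₁+f₂
matches the neuron's baseline firing rate r, producing a characteristic
triangular pattern in the second-order susceptibility with ridges at f₁=r,
f₂=r and the anti-diagonal f₁+f₂=r.  Whether real sensory neurons show this
structure — and why it is so hard to measure — is what this package's
simulation and analysis pipeline quantifies.

## The estimators

Spike trains are binned into rate-coded vectors (Δt = 0.5 ms, value 1/Δt in
bins containing a spike) and cut into N = 512-sample rectangular FFT segments
of T = 256 ms (resolution ≈ 4 Hz, no overlap).  With segment-averaged spectra
S_ss(ω) = (Δt/N)⟨S S*⟩ and cross-spectra S_xs(ω) = (Δt/N)⟨X S*⟩:

    χ₁(ω)        = S_xs(ω) / S_ss(ω)                          [Hz/%]
    S_xss(ω₁,ω₂) = (Δt²/N) ⟨X(ω₁+ω₂) S*(ω₁) S*(ω₂)⟩
    χ₂(ω₁,ω₂)    = S_xss(ω₁,ω₂) / (2 S_ss(ω₁) S_ss(ω₂))       [Hz/%²]

The susceptibility index condenses |χ₂| into one number: project |χ₂| onto
the diagonal by averaging anti-diagonals, find the peak of the projection
D(f) within ±50 Hz of the baseline rate r, and compare it with the mean of
flanking 10 Hz reference windows: SI = D(f_peak)/D_ref.  SI ≈ 1 means no
structure; SI > 1.8 reliably flags the triangular pattern.

The P-unit model is a stochastic LIF with threshold rectification of the
input, dendritic low-pass filtering (τ_d), spike-triggered adaptation
(τ_A, ΔA), Gaussian intrinsic noise of intensity D, and an absolute
refractory period, integrated with forward Euler at 0.05 ms.  The
Furutsu–Novikov noise split re-interprets 90 % of the intrinsic noise as a
band-limited RAM stimulus s_ξ(t) whose amplitude is bisected until the ISI
CV matches the baseline CV; cross-spectra against s_ξ then estimate the
susceptibilities in the vanishing-stimulus limit with drastically improved
signal-to-noise ratio.

## Worked example

```python
from spikesusc import (exemplar_punit, split_susceptibility, si_of_chi2,
                       ram_susceptibility)

cell = exemplar_punit()          # baseline ~76 Hz, CV ~0.21, locked to EOD
acc, split = split_susceptibility(cell, n_segments=10_000, seed=1)
si = si_of_chi2(acc.chi2(), split.target_rate_hz)
print(f"noise split: equivalent contrast {split.amplitude:.1%}, "
      f"SI(r) = {si.si:.2f}")

strong = ram_susceptibility(cell, contrast=0.10, n_segments=10_000, seed=7)
print(f"10% RAM:     SI(r) = {si_of_chi2(strong.chi2(), split.target_rate_hz).si:.2f}")
```

prints

    noise split: equivalent contrast 4.7%, SI(r) = 2.90
    10% RAM:     SI(r) = 1.14

The noise split reveals the ridge at f₁+f₂ = r (SI well above the 1.8
threshold) for this low-CV cell, while a strong external 10 % RAM linearizes
the response and flattens |χ₂| (SI near 1) — the central qualitative result
the pipeline reproduces.

A command-line interface wraps the same pipeline:

    spikesusc simulate --out runs/base --seed 1 --duration 10
    spikesusc noise-split --out runs/split --seed 1 --n-segments 10000
    spikesusc two-sine --out runs/sweep --seed 1 --df1 40
    spikesusc population --out runs/pop --n-cells 10 --cell-class punit_like

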