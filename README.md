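# courtentropy

Entropy analysis of badminton strike positions, for sports scientists and
match analysts who work with stroke-level event logs.  Where on the court do
players hit from, how predictable are those positions, and does that
predictability relate to winning points, leading the score, or the phase of
the match?

## The measures

The half court is partitioned into 12 zones (4 across the width x 3 from
net to baseline; zones 1, 4, 9, 12 are the corners).  Three quantifiers are
implemented:

- **Standard entropy** of a zone distribution — normalized Shannon entropy,
  `H = -Σᵢ pᵢ ln pᵢ / ln 12`, where `pᵢ` is the probability of striking from
  zone `i`.  `H = 0`: every stroke from one zone; `H = 1`: no positional
  preference.
- **Receiving entropy** — for each origin zone `i`, the standard entropy of
  the zone of the *next* stroke in the rally, i.e. how unpredictable the
  reply destination is, per origin.
- **Spatial entropy** (Clark–Evans ratio) — works on raw coordinates: for
  `N` strokes in a window of area `S`, `Hs = ⟨r⟩ / r_ran`, where `⟨r⟩` is the
  mean nearest-neighbour distance and `r_ran = ½√(S/N)` its expectation
  under complete spatial randomness.  `Hs ≪ 1`: clustered; `≈ 1`: random;
  up to the triangular-lattice ceiling `2√(2/√3) ≈ 2.149`: regular.

A two-strategy **mixture model** interprets the standard entropy: each
stroke follows a "four-corner" strategy with probability γ (uniform over
zones 1, 4, 9, 12) or a fully random one with probability 1−γ.  Each corner
zone then carries `p₄c = (1+2γ)/12`, each other zone `pₙ₄c = (1−γ)/12`, and

    H(γ) = -[4 p₄c ln p₄c + 8 pₙ₄c ln pₙ₄c] / ln 12

falls monotonically from 1 at γ=0 to ln 4/ln 12 ≈ 0.558 at γ=1, so an
observed mean entropy inverts to a γ̂ that locates a corpus between the two
pure strategies.

Because elite stroke logs are not public, the package ships a seeded
synthetic generator (`courtentropy.synthetic`) producing corpora with the
documented structure: corner-dominant zone shares (17 / 16 / 13.9 / 13 % for
zones 1, 9, 4, 12; 1.1 % for zone 10), rallies averaging 9 strokes,
best-of-three sets to 21 points, alternating strikers, running scores and
per-point winners — 259 matches ≈ 2.1 × 10⁵ strokes at the default scale.

## Worked example

```python
import numpy as np
from courtentropy import (SyntheticConfig, generate_corpus, zone_pdf,
                          standard_entropy, SplitSpec, per_match_entropy,
                          paired_t_test, fit_gamma, zone_distribution)

ds = generate_corpus(SyntheticConfig(n_matches=259, seed=42))
pdf = zone_pdf(ds.matches)
print(f"{ds.total_strokes} strokes; corners hold "
      f"{100 * pdf.probabilities[[0, 3, 8, 11]].sum():.1f} % of them")

won, lost, _ = per_match_entropy(ds.matches, SplitSpec(kind="won_vs_lost"))
t = paired_t_test(won, lost)
print(f"won H = {t.mean1:.4f}, lost H = {t.mean2:.4f}, p = {t.p_value:.3f}")

h = np.mean([standard_entropy(zone_distribution(list(m.strokes()))).H
             for m in ds.matches])
print(f"mean per-match H = {h:.4f} -> gamma_hat = {fit_gamma(h).gamma_hat:.2f}")
```

prints

```
212108 strokes; corners hold 60.0 % of them
won H = 0.9197, lost H = 0.9207, p = 0.319
mean per-match H = 0.9231 -> gamma_hat = 0.45
```

So on this null corpus (winners and losers drawn from the same zone
distribution) the won/lost entropy distributions overlap — the paired t-test
finds no difference — and the corpus's mean entropy corresponds to a
45 % four-corner / 55 % random strategy mixture.

## Analysis scripts

The numbered drivers under `analysis/` run the full study pipeline over the
synthetic corpus and write their tables to `results/`:

| script | what it does |
| --- | --- |
| `01_generate_corpus.py` | generate the 259-match corpus; stroke-log CSV to `scratch/` |
| `02_zone_distribution.py` | pooled zone shares and pooled standard entropy |
| `03_standard_entropy_splits.py` | per-match won/lost standard entropy + paired t-test |
| `04_receiving_entropy.py` | receiving-zone entropy profile per origin zone |
| `05_spatial_entropy.py` | reference regimes (clustered/random/lattice) and spatial-entropy splits |
| `06_gamma_sweep.py` | Monte Carlo γ sweep (Δγ = 0.01, 100 reps), analytic overlay, γ̂ fit |

Run them from `analysis/` in any order; each regenerates the corpus
deterministically.

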