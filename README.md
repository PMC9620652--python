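# sparsesig

Detection of the ganciclovir-associated mutational signature (GCVsig) in
**sparse targeted-panel somatic mutation catalogs**.

Ganciclovir (GCV), an antiviral widely given to transplant patients, is a
guanine analogue that is misincorporated into genomic DNA and leaves a highly
distinctive mutational signature dominated by C>A substitutions with a 3'
adenine ("CA>AA" changes). Panel sequencing yields very few mutations per
sample (often < 10), so naive signature refitting attributes spurious
exposure to GCVsig by sampling noise alone — especially when a genuine
process that resembles it (SBS18; SBS38 in skin) is active. `sparsesig`
implements a simulation-calibrated detection procedure that controls this
error, plus the companion analyses: replication-strand asymmetry of C>A
mutations and trinucleotide accessibility of driver hotspots.

Intended users: cancer-genomics analysts screening panel cohorts for
drug-associated mutagenesis, and methods developers who need a reproducible,
fully synthetic benchmark of sparse-spectrum signature detection.

## Method

For a sample with channel counts $x \in \mathbb{N}^{96}$ and a fixed
column-stochastic catalog $P \in \mathbb{R}^{96 \times K}$, exposures
$e \in \Delta^{K-1}$ maximize the multinomial log-likelihood

$$\ell(e) = \sum_c x_c \log\Big(\sum_k e_k P_{ck}\Big)$$

via EM (deterministic, uniform start). The GCVsig **contribution score** is
$e_{\mathrm{GCVsig}}$.

**1% FDR cutoff.** Null spectra are simulated as multinomial draws from a
0.95 SBS18 + 0.05 SBS5 mixture (SBS38 instead of SBS18 for skin), refitted,
and the 99th percentile of the null GCVsig score — per mutation count
$X_{\mathrm{count}}$ — is the score above which a null sample is flagged
with 1% probability. For samples whose mutations come from several
processes, the cutoff is priced by an OLS surface fitted to simulations over
null contributions 0.05–0.95 and counts 5–250:

$$\mathrm{cutoff} = \beta_0 + \beta_1 X_{\mathrm{count}}
 + \beta_2 \log X_{\mathrm{count}} + \beta_3 X_{\mathrm{contrib}}
 + \beta_4 X_{\mathrm{contrib}} \log X_{\mathrm{count}}$$

with $X_{\mathrm{contrib}}$ estimated per sample by its CA>AA fraction
(used when the sample has > 10 CA>AA mutations; otherwise the 0.95-mixture
curve applies). Samples with < 10 mutations are not evaluable. Skin samples
must clear both the SBS18- and SBS38-null cutoffs.

Cohort-level error control: per-sample chi-square tests of the observed
GCVsig frequency ($\mathrm{score} \times X_{\mathrm{count}}$) against the
expectation under the cohort-average spectrum, Benjamini–Hochberg adjusted;
and a permutation FDR that replaces every spectrum by a draw from the
cohort average and repeats the calls 10 times.

## Worked example

```python
import numpy as np
from sparsesig import (CohortSimSpec, GcvSignatureDetector,
                       make_signature_catalog, make_cohort)
from sparsesig.channels import channel_for

catalog = make_signature_catalog("cosmic_like", np.random.default_rng(123))
spec = CohortSimSpec(n_samples=200, spike_in_fraction=0.02,
                     spike_in_exposure=0.8, seed=42)
mutations, truth = make_cohort(spec, catalog)

detector = GcvSignatureDetector(
    catalog,
    curve_reps=1000, curve_counts=[10, 30, 100, 300, 1000],
    surface_reps=300, surface_contribs=[0.1, 0.3, 0.5, 0.7, 0.9, 0.95],
    surface_counts=[10, 50, 120, 250], random_state=0,
).fit()

counts = np.zeros((len(truth), 96), dtype=int)
idx = {s: i for i, s in enumerate(truth["sample_id"])}
for row in mutations.itertuples():
    counts[idx[row.sample_id], channel_for(row.context, row.alt)] += 1

positive = detector.predict(counts, cancer_groups=truth["cancer_group"])
print(truth["sample_id"][positive].tolist())
print(truth[truth["spiked"]]["sample_id"].tolist())
```

prints

```
['S0017', 'S0087', 'S0130', 'S0153']
['S0017', 'S0087', 'S0130', 'S0153']
```

— the four spiked samples (GCVsig exposure 0.8) are called, and nothing
else. Their fitted scores (0.69–0.86) sit far above the calibrated cutoffs
at their mutation counts (0.11–0.20); the 0.95-mixture cutoff curve itself
falls from 0.59 at 10 mutations to 0.05 at 1000, quantifying how much
signal a sparse sample must show before a call is safe. The fitted SBS18
regression surface reproduces its training cutoffs with $R^2 \approx 0.98$.

The same pipeline is scriptable from the shell:

```bash
sparsesig simulate --spec sim.yaml --out data/
sparsesig calibrate --catalog data/catalog.tsv --out calib/ --seed 0
sparsesig call --mutations data/mutations.tsv --catalog data/catalog.tsv \
               --calib calib/ --out calls.tsv
```

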