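# Methods

## The quantification problem

A transgene too large for one AAV capsid is split across a 5' vector
(promoter, intron, Kozak, N-terminal coding half) and a 3' vector
(C-terminal half, polyA) that share an 800 bp homologous overlap.  In the
nucleus the two genomes either reconstitute the full cassette by homologous
recombination (HR) across the overlap, join end-to-end into ITR-mediated
concatemers (head-to-tail, head-to-head or tail-to-tail), or persist as free
monomers.  Dosing and safety hinge on how much of the delivered material ends
up in each fate, so the package implements the droplet-digital-PCR (ddPCR)
design that measures it:

* **VCN** (vector copy number): each vector's unique-region concentration
  over the Titin host reference, times ploidy 2 — vg per diploid genome.
* **HR efficiency**: concentration of the overlap-spanning REC amplicon over
  the concentration of the *limiting* (less abundant) single vector,
  `100 × rec / min(c5, c3)`.  The limiting vector bounds the number of
  recombination events, hence the denominator.
* **Concatemer fraction**: summed junction-assay concentration over the
  summed vector concentrations, `100 × Σ junc / (c5 + c3)`.
* **Expression specificity**: transcript-class concentrations from an RT
  reaction, with a verdict that expression derives from the reconstituted
  cassette only.

Absolute concentration follows standard digital-PCR statistics: with k of N
droplets positive, λ̂ = −ln(1 − k/N) copies per droplet and
λ̂/v_droplet × dilution copies/µL.  The 95% CI is the delta-method normal
approximation λ̂ ± 1.96·√(k/N / (N(1−k/N))); an exact Clopper–Pearson option
exists for single concentrations.  Ratios (VCN, HR%, concatemer%) propagate
first-order (delta-method) variances; the min() selection in the HR
denominator is treated as fixed, which is accurate whenever the two vector
concentrations are well separated (they are, under the default 8 vs 12
vg/genome conditions).

## Why two restriction enzymes

The REC primer pair flanks the whole overlap (50 bp on each side; 900 bp on
the intact HR product) and so cannot distinguish a recombined molecule from a
head-to-tail concatemer, where the amplicon simply runs across the two fused
ITRs (~1990 bp with the default geometry, still amplifiable).  **SmaI** cuts
once inside every ITR; HR resolves the internal ITRs away, so pre-digestion
severs the concatemer template but not the HR product.  Skipping SmaI
therefore *inflates* HR estimates — the pipeline lets you run that protocol
deliberately (it annotates the report) to demonstrate the bias.

**AleI** cuts exactly once per vector unit, outside the ITRs and the overlap,
so after digestion every fragment spans at most one ITR junction and every
junction amplicon is PCR-sized regardless of chain length.

## The junction panel and its attribution convention

Four outward-facing primers cover the four unit ends: A and B sit *inside*
the overlap (present on both vectors) pointing toward the overlap-proximal
ITRs, with A placed distal to B so that on an HR molecule — where the overlap
occurs once and no ITRs intervene — the pair is divergent and silent.  C and
D sit at the opposite ends.  Every ITR junction then presents exactly one
convergent pair over {A,B,C,D} (a palindromic flip junction presents one
primer self-paired), and a pure-HR molecule presents none.

With free unit identities and orientations there are ten junction end-pair
classes, and no grouping of the four primers into four physical pairwise
reactions can count each class exactly once (each primer would have to appear
in exactly one reaction, which cannot cover the cross-primer classes).  The
panel's four assays therefore use a *first-primer attribution*: a junction is
credited to the alphabetically first primer of its unique convergent pair
(A: AA/AB/AC/AD; B: BB/BC/BD; C: CC/CD; D: DD).  This is bookkeeping, not
chemistry — the physical EvaGreen multiplex cannot attribute amplicons either
— and it makes the four single assays a disjoint, complete cover, so the
multiplexed count equals their sum identically and the concatemer estimator
is insensitive to how the classes are split.

## The synthetic-data generator

`simulate_sample` draws, per sample: unit totals T5 ~ Poisson(u5·H),
T3 ~ Poisson(u3·H) for H diploid genomes; R = round(θ·min(T5,T3)) HR
products, each consuming one unit of each identity; then a fraction φ of the
remaining units enters concatemer chains with geometric lengths (support
≥ 1, mean 1/p; length-1 draws stay monomeric), identities sampled
proportional to the remaining pools; the rest stays monomeric.  Ground truth
(unit totals, HR count, junction census) is tallied during generation,
independently of the species table, and `ground_truth_metrics` re-derives it
from the table alone — estimator recovery is tested against this bookkeeping.

Junction orientations follow a feasibility-restricted draw: a chain end
exposing a *head* (3'-terminus) can form head-to-tail or head-to-head
junctions; one exposing a *tail* can form head-to-tail or tail-to-tail.
Consecutive flip junctions therefore alternate head-to-head/tail-to-tail, as
they must on a physical linear chain, which also means the *marginal* type
frequencies cannot match an arbitrary weight vector; the contract that is
well-posed (and tested) is conditional: among junctions formed from an
exposed head, head-to-tail vs head-to-head splits as w_ht : w_hh, and
likewise from an exposed tail.

Ground-truth HR is defined exactly as the estimator's estimand,
R/min(T5,T3): the assay itself is the operational definition of efficiency,
so recovery tests are well-posed.  The true concatemer fraction is the
ITR-junction count over all units; after AleI every junction in a linear or
circular chain is detectable, so this equals the assay-detectable fraction.

Transcripts: recombined ~ Poisson(r·R); 5'-leak ~ Poisson(ε·(T5−R)) — every
5' unit not consumed by HR keeps its promoter, monomeric or concatemerized —
and the promoterless 3' vector contributes structurally zero.  RT assays are
modeled as transcript-class-specific (junction-spanning designs); a
5'-region assay that also counted the recombined mRNA would make the
specificity verdict ill-posed.

### Defaults (the study conditions)

| parameter | default | meaning |
|---|---|---|
| u5, u3 | 8, 12 vg/diploid genome | delivered load; 5' < 3' mirrors the in vivo VCN asymmetry |
| θ (`hr_fraction`) | 0.5 (TA/GA-like), 0.25 (diaphragm-like) | fraction of the limiting vector consumed into HR |
| φ (`concat_fraction`) | calibrated | `concat_fraction_for_target(0.04, …)` sets the expected junction fraction to 4% |
| `chain_length_p` | 0.5 | geometric chain length, mean 2 units |
| `orientation_weights` | (⅓, ⅓, ⅓) | junction-type draw over the feasible set |
| `host_genomes` | 2000 | diploid genomes per sample |
| droplets | 20,000 × 0.85 nL | standard QX geometry; with the whole sample partitioned, λ per class = count/N, putting all defaults at λ ≈ 0.1–1.2 |
| amplitude model | baseline 1000, level unit 2000, noise σ 100 | FAM: FIVE×1/THREE×2; VIC: REC×1/TTN×2; thresholds at level midpoints |
| ε, r | 0.02, 2.0 | transcript leak and expression rates per template |

φ = target·T/((1−p)(T−2R)) in expectation, since each chained unit
contributes 1−p junctions on average.

### What the generator does and does not emulate

It reproduces the statistical structure the estimators assume: Poisson
sampling of delivered genomes, the three molecular fates with exact
bookkeeping, complete digestion, independent Poisson droplet loading,
well-separated amplitude clouds, and clean minus-RT controls.  It does not
model partial digestion, PCR efficiency or competition, rain (intermediate
amplitudes), droplet coalescence, cross-sample contamination, nuclear
trafficking or dose–response.  Passing tests therefore validate the
estimators and the digestion/panel logic under the assay's own assumptions —
not robustness to those real-data artifacts.

## Numerical and design choices

* Coordinates are 0-based, half-open, on each construct's coding strand;
  minus-oriented units are mirrored exactly (a primer pair amplifies either
  template orientation — on a mirrored unit the declared reverse primer is
  the left-hand member of the convergent pair).
* Element lengths are stand-ins summing to ≤ 4.7 kb (the AAV capacity) while
  honoring the printed anchors: 800 bp overlap, 900 bp intact REC amplicon.
  The true codon-optimized sequence is proprietary; `realize_sequence` emits
  deterministic pseudo-random sequence with the SmaI/AleI recognition sites
  planted only at the declared coordinates (spurious matches are resampled
  deterministically and audited) for FASTA/BED export.
* Digestion is complete and operates on structural coordinates; realized
  sequences are export-only.  Maximum amplicon 2500 bp for genomic assays
  (so an undigested head-to-tail junction *is* REC-amplifiable — the bias
  SmaI exists to remove), 250 bp for RT assays.
* Per-class droplet occupancy above λ = 10 raises a saturation error
  (mis-scaled input); an all-positive assay raises at estimation time.
  Degenerate references (no Titin signal, absent limiting vector) are fatal
  in the individual estimators but only flagged at report level, so an
  all-negative control sample still yields a report of zero concentrations.
* Amplitude gating decodes integer level sums via strictly increasing
  thresholds; a channel's levels must have distinct subset sums (the default
  ×1/×2 pairs give sums 0–3).  With zero noise, amplitude gating reproduces
  calls mode exactly, a tested invariant.
* The concatemer percentage uses Poisson-corrected copies/µL (the Methods
  formulation); a raw-droplet-count variant is available behind
  `raw_droplets=True` for comparison.
* A single scenario seed fans out into stage-specific substreams
  (simulation, each reaction's partition and noise, transcript draws), so
  runs are byte-identical under a fixed seed and stages can be re-run
  independently.

## Problem sizes used in the test and acceptance studies

Estimator-calibration studies use 1000 Monte-Carlo replicates of 20,000
droplets per occupancy level; recovery studies use 100 seeded end-to-end
runs per condition at 20,000 droplets with 2000 host genomes (~40,000 vector
units); the conservation sweep uses 10,000 small random populations.  These
sizes give standard errors an order of magnitude below every asserted
tolerance while keeping the full suite inside a few minutes on one core.

## Known limitations

* Concatemer chains and HR products are disjoint molecule classes; chimeric
  chains containing an HR junction are representable in the data model but
  not generated.
* Episomal circles are supported (and counted correctly after AleI) but off
  by default; the assays modeled here cannot distinguish them from linear
  chains after digestion.
* CIs are first-order normal approximations; at very low counts (k ≲ 10) the
  exact binomial option is preferable.
* Absolute copies/µL depend on the declared sample volume and dilution; all
  headline quantities are ratios and independent of that scaling.
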