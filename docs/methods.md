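# Methods

## The measurement model

The package models data from an amine-reactive, homobifunctional
crosslinker with three engineered properties:

* **Isotopic coding.** The reagent is used as a 1:1 mixture of a light
  form and a heavy form carrying `n_label_sites = 8` deuterium atoms, so
  every crosslinker-containing species appears twice in MS1, separated
  by `8 × (m(²H) − m(¹H)) = 8.050214 Da` (reported as 8.0502). The two
  forms co-elute almost perfectly, with the deuterated form eluting
  slightly earlier on reversed phase — hence the asymmetric RT window.
* **CID cleavability.** The spacer breaks at two labile bonds under
  collisional activation, leaving a *short-arm* remnant on one peptide
  and a *long-arm* remnant on the other. For an inter- or intra-protein
  link this predicts four diagnostic neutrals — pepA+short, pepA+long,
  pepB+short, pepB+long — satisfying the conservation identity
  `(pepA+short) + (pepB+long) = precursor + cleavage_adjustment`
  (the adjustment is a single configured constant absorbing any
  proton/water transfer; zero for the bundled synthetic reagent).
  A dead-end species yields the two single-peptide signature ions; a
  loop-link yields the opened-loop ion carrying both arms.
* **Affinity tag.** Enrichment itself is upstream wet-lab work; the
  pipeline only assumes crosslinker-containing species dominate.

Link chemistry: Lys side chains and the protein N terminus are reactive;
the C-terminal Lys of a tryptic peptide is still considered linkable.
Species kinds are `inter` (two peptides, two proteins), `intra` (two
peptides, one protein), `loop` (one peptide, two sites) and `single`
(dead-end, one site, quench type hydrolyzed or ammonium-quenched).

The exact spacer, arm and dead-end masses of commercial reagents are
supplier-specific and must be given in a config file. The bundled
`synthetic_crosslinker()` (spacer 509.0970 = 200.0000 + 309.0970 Da,
hydrolyzed/ammonium dead-ends, 4/4 deuterium split across the arms) is a
*synthetic* reagent with the correct structure, used by the generator
and the test suite; it is not a stand-in to be used on real data.

## MS1 doublet criteria

A feature pair (light, heavy) is a doublet when **all** of the following
hold (boundaries inclusive):

| criterion | default | unit |
|---|---|---|
| mass delta | 8.0502 ± 0.01 | Da |
| RT offset (heavy − light apex) | [−0.4, +0.05] | min |
| log₂ (heavy/light summed intensity) | 0 ± 2 | — |
| both maximum intensities | ≥ 25 000 | counts |

An alternative "pipeline" preset replaces the log₂/floor cuts with a 20%
relative-intensity tolerance. Pairing operates on neutral deconvoluted
masses within equal charge only. When a feature pairs with several
candidates, edges are chosen greedily by smallest |mass error|, then
smallest |RT delta|; chains of pairwise-accepted features become
multiplets, capped at order 4 (longer chains split from the light end).
The sweep-based pair search is exactly equivalent to testing all ordered
pairs (property-tested against the O(n²) oracle). Inclusion lists emit
both partners of every multiplet of charge ≥ 3, with a 0.5 min RT pad
and deduplication on (m/z to 4 dp, charge).

## Decoy construction

Decoys shuffle each protein *within its fully-tryptic peptides* (zero
missed cleavages), holding fixed: each peptide's C-terminal residue, all
internal (proline-suppressed) K/R, any Pro directly following a K/R, and
keeping Pro out of post-K/R positions it did not occupy. This preserves
protein length, the complete tryptic boundary set, and every peptide's
residue multiset — so decoy peptides match targets in number, length and
composition, the property target-decoy competition relies on. Shuffles
reproducing the original peptide are retried (up to 10×) when at least
two distinct residues are movable; degenerate peptides pass through.

## The internal matcher

The built-in matcher is a deliberately small stand-in for a full search
engine, adequate for synthetic and desk-scale data: candidates of all
four kinds (and both labels) are enumerated within 10 ppm of the
precursor neutral mass over a mass-sorted peptide index (≤ 3 missed
cleavages, fixed carbamidomethyl-Cys); fragments are singly-charged b/y
ions with the partner peptide plus spacer treated as a fixed mass on the
linked residue (loop-links suppress fragments between the linked sites);
the score is −log₁₀ of a binomial tail on matched vs theoretical ion
counts with the per-ion match probability taken from observed peak
density (fragment tolerance 0.02 Da). Ties at rank 1 are broken by
matched fraction, then by matched crosslinker cleavage-product count —
necessary because peptide pairs that differ only by a terminal residue
swapped between partners have *identical* theoretical b/y mass sets —
and finally lexicographically for determinism. The reported delta score
is taken against the best candidate with a different peptide pair, so
link-site variants of one pair do not zero it.

## Feature vector and rescoring

Each PSM is encoded as 41 features (plus the five identification
columns of the PIN format): search score, delta score, per-peptide
scores/ranks, matched fraction, precursor deconvolution score and mass
error, label class, charge, precursor mass, TIC, base-peak m/z and
intensity, peptide lengths, link-type indicators, H/L ratio, partner RT
delta, isotope-pattern flag (cosine ≥ 0.95 against a Poisson-averagine
envelope when an observed envelope is available), multiplet order,
MS1/MS2 label agreement, the four cleavage-product flags with count and
summed intensity, dead-end signature, partner corroboration (an
opposite-label PSM of the same species whose precursor differs by the
label delta within 0.02 Da), total missed cleavages, and paired
missing-evidence indicators. Missing evidence is encoded as 0 with the
indicator set to 1, never NaN, and the schema is identical regardless of
which evidence is absent.

Rescoring is Percolator-style semi-supervised learning: features are
standardized; the starting ranking is the single feature/sign that
accepts the most targets at q ≤ 0.01; within each of 3 cross-validation
folds the procedure iterates (10×): targets at q ≤ 0.01 become
positives, all decoys negatives, a ridge-regularized least-squares
discriminant (α = 1) is fitted and the training split rescored. Each
fold keeps the iteration that accepted the most training targets and
falls back to the starting feature if no model beat it — the safeguard
that makes small-n behaviour stable. Held-out folds are scored by their
training model and calibrated against the training decoy score
distribution before merging. With fewer than 20 targets or decoys the
single-feature ranking is used directly (logged).

q-values use the conservative target-decoy estimator
`FDR(s) = (decoys ≥ s + 1) / max(1, targets ≥ s)` with monotonization
from the worst score upward; decoys inherit the q of the next better
target. Acceptance is q ≤ 0.02 inclusive, applied per link-type stratum
by default (inter, intra, loop, single each compete against their own
decoys); a pooled mode exists and is appropriate when strata are too
small to support the (d+1)/t floor — a stratum of fewer than 50 targets
cannot reach q ≤ 0.02 even with no decoy above it.

Accepted PSMs collapse to residue links keyed by (protein, site,
protein, site) in canonical order, with loop-links counted as
intra-protein pairs and dead-ends carrying no residue pair; links
aggregate to one record per unordered protein pair with total and
per-fraction PSM counts, unique residue-pair and peptide-pair counts.

## Structural validation

Links are resolved on PDB/mmCIF models by author residue numbering (no
sequence realignment; an unmatched residue is reported, not guessed).
The Cα–Cα Euclidean distance is computed over all equivalent chain
copies given in the accession→chains mapping and the **minimum** is
reported — the shortest-constraint rule for homodimers, generalized to
any number of copies. A link is `within_span` when the distance is at
most the crosslinker maximum (38 Å default). The null distribution is
built from uniformly random residue pairs (optionally restricted to Lys
and chain-initial residues), deterministic under seed, binned at 2 Å.

## The synthetic-data generator

`simulate_ground_truth` draws random proteins (uniform residue model
with Lys boosted to 8% so linkable and cleavage sites are plentiful;
every protein has ≥ 2 Lys), digests them (≤ 1 missed cleavage, length
5–25) and plants the requested numbers of inter/intra/loop/dead-end
species on valid reactive sites, with charges uniform on 3–5 and RT
apexes uniform on 10–100 min. Loop species never span the entire
peptide (such species have no b/y ion outside the loop and are
unidentifiable in principle).

`emit_ms1_feature_table` writes one light+heavy feature pair per species
satisfying every doublet criterion with margin (mass error within ±60%
of tolerance, RT offset in the central 80% of the window, log₂ ratio
N(0, 0.5) truncated at ±1.8, log-normal intensities above the floor); a
configurable fraction of pairs instead violates exactly one named
criterion, and unpaired noise features can be added.
`emit_ms2_spectra` writes one centroided spectrum per species and label,
with b/y ions subsampled at a coverage fraction, cleavage products
included with a given probability, and uniform-m/z noise peaks; output
as minimal standard-conformant mzML (uncompressed 64-bit floats) or a
binary-free JSON format for fast tests.

`simulate_rescoring_dataset` works at the PSM-feature level for FDR
calibration: true targets carry signal in the score and the
crosslinker-specific features (cleavage-product count Binomial(4, 0.85)
vs 0.10 under the null, corroboration 0.7 vs 0.05, matched fraction
Beta(6, 2) vs Beta(1.5, 6), label agreement 0.9 vs 0.3); false targets
and the equally-sized decoy set are drawn from one null distribution —
the exchangeability assumption underlying target-decoy competition.

What the generator does **not** emulate: chimeric spectra, correlated
noise, retention-time drift and prediction, isotope-envelope shapes
beyond the pattern flag's needs, fraction chemistry (fraction labels are
tags), or realistic score distributions of a production search engine.
Passing closed-loop tests therefore demonstrates the pipeline's internal
consistency and statistical calibration, not its performance on real
spectra.

## Problem sizes and numerical choices

Closed-loop tests run 8 proteins × ~250 residues with 130 planted
species (260 spectra) — small enough for exhaustive oracles, large
enough that 2% FDR acceptance is possible at all (the (d+1)/t estimator
needs ≥ 50 accepted targets). Calibration checks use 20 seeded
populations of 500 true + 5000 false targets with matched decoys.
Tolerances: fragment and cleavage-product matching 0.02 Da inclusive;
precursor and MS1-evidence matching 10 ppm; corroboration 0.02 Da.
All randomness flows through `numpy.random.default_rng` seeds;
identical seeds give byte-identical FASTA/mzML output.

## Known limitations

* Singly-charged fragment ions only in the internal matcher; no
  ETD/EThcD ion types, no open modification search, no chimera handling.
* Met-oxidation is pass-through only (no variable-modification search
  space management).
* Structure mapping requires author-numbering agreement; no
  Needleman–Wunsch remapping of constructs.
* The external-engine reader targets Kojak 1.5.x column names
  (configurable); rows missing diagnostics get zeroed features with
  missing-evidence indicators.
* mzML I/O covers the centroided-MS2 subset this pipeline needs, not
  the full standard.
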