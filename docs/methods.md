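# Methods

`dirpscan` identifies **divergent-but-interacting paralog pairs (DIRPs)** —
paralogs that are far apart in sequence/phylogeny yet significantly close in a
protein–protein interaction (PPI) network — then finds alignment positions
specifically conserved within those pairs and maps them onto protein-complex
binding interfaces.  This note records the models, the parameters that matter,
the numerical conventions, and the design choices made where the design was
genuinely open.

## Network proximity by Laplacian kernels

An interaction network is an undirected simple graph over protein identifiers
(self-loops dropped, duplicates collapsed).  Hubs — nodes with degree ≥ 300 by
default — are removed in a single pass before any kernel computation, because
highly connected nodes short-circuit every path and wash out specific
proximity.  The removal is deliberately not iterated: degrees are evaluated on
the input graph only.

Node similarity is measured with two kernels of the combinatorial Laplacian
`L = D − A`, computed spectrally on the largest connected component with
lexicographically ordered nodes (so outputs are bit-stable):

* **Diffusion kernel (DK)** `K = exp(−βL)`.  β is a bandwidth with no
  canonical value; the default is β = 1.0 and it is exposed in every API.
  Sensitivity: at β → 0 the kernel approaches the identity (no information);
  as β → ∞ every row approaches the uniform component average (all
  information lost); intermediate β trade locality against smoothing, and the
  DIRP selection is rank-based (a null quantile on the same kernel), which
  removes most of the scale dependence.
* **Commute-time kernel (CT)** `K = L⁺` (Moore–Penrose pseudo-inverse).  The
  derived commute time `C(i,j) = 2m (K_ii + K_jj − 2K_ij)` equals the expected
  round-trip length of a simple random walk; on trees `C/2m` reduces exactly
  to the unit-resistance path length.  Both facts are exploited as independent
  test oracles (a pure random-walk simulator, and exact path counts).

Kernel similarities become distances through a cosine normalisation
`p_ij = K_ij / sqrt(K_ii K_jj)` followed by `d = −ln p`.  For a PSD kernel
Cauchy–Schwarz gives `p ∈ (0, 1]`, hence `d ≥ 0` and `d_ii = 0`.  The
normalisation is a design choice (row-normalised and min–max variants would
also produce probabilities); the cosine form was chosen because it is the only
one of the three that guarantees the probability bounds for every PSD kernel
with no data-dependent constants.  `L⁺` can carry small negative off-diagonal
entries; probabilities are floored at 1e−12 before the logarithm, making such
pairs effectively infinitely distant.  Pairs spanning different components
after hub removal are *unreachable*: they carry no distance and are excluded
from DIRP candidacy (and from both numerator and denominator of selection-rate
reports).

## Phylogenetic distances

Patristic distances (branch-length sums along the unique leaf-to-leaf path)
are computed from Newick trees with mandatory non-negative branch lengths.
Plain patristic distance is the default; division by tree height is available
as a flag.  For joint plotting with `−ln p` network distances the raw
distances are rescaled with `d′ = exp(λd) − 1`, a strictly monotone transform
with `d′(0) = 0` that stretches the divergent tail; λ defaults to 1 and only
affects presentation, never pair ranking.  The sequence-identity filter (not
the phylogenetic transform) is the operative divergence gate, with the
normalised-distance boundary (default 1.7, the value that tracks the 45%
identity line in the real Ras data) available as an optional secondary gate.

## Null models and empirical significance

The network null permutes each node's partners while preserving its degree:
double-edge swaps with rejection of self-loops and duplicate edges, attempting
`10·|E|` swaps per replicate, 100 replicates by default.  Candidate-pair
kernel values are pooled across replicates (a per-pair null is available); the
closeness cutoff is the `1 − α` empirical quantile (type-7, linear
interpolation) of that pooled null at α = 0.05.

Empirical p-values use the add-one permutation estimator
`p = (r + 1)/(n + 1)` with ties counted as extreme.  With 100 replicates the
smallest attainable p is 1/101 ≈ 0.0099; significance below 0.01 therefore
requires the observed statistic to beat *every* replicate.  This discreteness
is a real limitation (see below).

## DIRP selection

A pair enters the DIRP set of a (network, kernel) combination when its
pairwise identity over mutually non-gap columns is ≤ 45% — the regime BLOSUM45
was designed for — **and** its kernel similarity in the real network is at
least the null cutoff.  The closeness test is applied on the similarity scale
(values ≥ cutoff), not on the −ln scale.  Selection is performed independently
per kernel, and the accounting (initial pairs → reachable → after identity →
selected) is emitted alongside.  Shared-interactor counts `|N(a) ∩ N(b)|`
(excluding the pair members) and their set-level median summarise how much
interaction context the selected pairs actually share.

## Differential position conservation

Every alignment column where the reference row (HRas for the Ras family) is
non-gap is scored in reference numbering ("Y32" = reference residue Y at the
32nd non-gap reference position).  Conservation of a pair set at a column is
the mean BLOSUM45 score of the two aligned residues over the set's pairs; raw
matrix integers are used deliberately (no diagonal normalisation), which makes
the differential statistic exactly invariant to adding a constant to the whole
matrix.  Pairs with a gap at the column are excluded from that column's mean
rather than penalised; columns scorable for fewer than 50% of the set's pairs
are left unscored.

The differential statistic is `delta(r) = C_set(r) − C_bg(r)`, with the
background mean taken over *all* alignment pairs.  Its null distribution comes
from random pair sets of the same size drawn from the same universe; the
p-value is the add-one fraction of null deltas at least as extreme in absolute
value (two-sided, because both hyper-conserved and hyper-variable positions
are of interest; direction is the sign of delta).  The default null is
per-position; pooling null deltas across positions is available by flag.  No
multiple-testing correction is applied by default, mirroring the per-position
p < 0.01 convention of the original Ras analysis; a Benjamini–Hochberg option
exists in the calling code's hands via the returned p-values.

## Structures, SASA and interfaces

PDB text is parsed with Biopython (altloc resolved to highest occupancy,
waters dropped) into a light structure model carrying Bondi-type van der Waals
radii by element.  SASA is computed in-house by the Shrake–Rupley method with
a deterministic golden-spiral point set — 960 points per atom, probe radius
1.4 Å — and is validated against the analytic two-sphere overlap formula
(≤ 1% of the full sphere area) and cross-checked against an independent
implementation.  A residue of the designated Ras chain belongs to a complex's
binding interface when `SASA(chain alone) − SASA(in complex) >` 1.0 Ų
(strict; the threshold is unstated in the field's tabulations and is
config-exposed).  The unbound state uses the chain conformation taken from the
complex, not a separate apo structure.

Complexes are clustered by Cα RMSD (Kabsch superposition on residues with
common author numbering, single linkage, cutoff 1.0 Å), with
sequence-identical structures merging first.

Overlap of a query position list with interfaces is tabulated two ways —
per complex (match count and share of the interface) and per position (number
of matching complexes) — and the two views are consistent by construction.
Percentages per complex are rounded with exact halves going *down* to one
decimal, the convention of the reference tabulation.  A position that is not
buried itself is *flanked* when both sequence neighbours (i−1 and i+1) are
buried, each in at least one complex; requiring a single complex to bury both
neighbours is available as an option (with the curated Ras interface lists the
union rule is the one that reproduces the published participation counts).
Functional-region assignment uses the classical HRas regions (Switch I 30–38;
Switch II 60–76; hypervariable C-terminus 166–189; nucleotide site
10–17, 28, 35, 57–60, 116–120, 145–147) with multi-membership allowed and
integer percentages (halves up).

### Curated Ras annotations

`dirpscan.ras_annotations` ships the binding-interface residue lists of 21
human Ras complex groups in shared HRas-equivalent numbering, the 22
positions specifically conserved in the divergent-but-interacting Ras pairs,
and the region map.  One curation decision is worth noting: the Exo84–RalA
interface (1ZC3) is deposited in RalA numbering, which runs eleven ahead of
HRas in that region; its buried aromatic F82 is stored as HRas-equivalent
position 71.  With that equivalence every published per-complex overlap ratio
is reproduced exactly; the per-position view then credits Y71 with six
complexes where the published ranked list shows five (the published tables'
own two views differ by exactly this one count).  The single hyper-variable
position is curated as I139 (the running text of the original analysis calls
it R139; the discrepancy is preserved as a note, not resolved).

## Synthetic study system

The generator's defaults are the package's reference conditions:

| parameter | default | why |
| --- | --- | --- |
| background nodes / attachment | 300 / 2 | scale-free-ish interactome at desk scale |
| family members | 35 | size of the human Ras paralog family |
| planted pairs / shared partners | 10 / 3 | 3 = shared-interactor median of real DIRPs |
| private partners per member | 3 | sparse, hub-free family wiring |
| alignment length | 160 | Ras G-domain scale |
| substitution rate × tree depth | 1.2 × 1.0 | cross-clade identity ~15%, within-clade spread through the 45% boundary |
| planted conserved / variable columns | 6 / 1 | positive and negative conservation controls |

Planted pair members sit in opposite basal clades of an ultrametric
coalescent-style tree, so planted pairs are always sequence-divergent;
background partner assignments are drawn without replacement, so non-planted
family pairs share exactly zero partners.  Sequence evolution is a uniform
per-site substitution process (no codon model, no indels — the synthetic MSA
is gapless, so gap handling is exercised by hand-built fixtures instead).
Planted conserved columns carry a per-pair residue (different across pairs:
conservation is within-pair, not family-wide); the variable column carries
tryptophan family-wide with one cysteine per planted pair, giving a strongly
negative within-pair score against a strongly conserved background.

Toy complexes are two chains of single Cβ-level carbon spheres on an extended
backbone (3.8 Å spacing); the partner hovers 5.5 Å above the designated
contact residues, which puts contacts inside the mutual occlusion radius
(1.7 + 1.7 + 2×1.4 = 6.2 Å) and sequence neighbours (√(3.8² + 5.5²) ≈ 6.7 Å)
outside it, so the designed contact set is recovered exactly at the default
ΔSASA threshold.

What the synthetic system does *not* emulate: alignment gaps, indel history,
correlated substitution processes, realistic interactome rewiring dynamics,
protein folds.  Passing the synthetic suite shows the machinery recovers
planted signal under the stated noise model; it does not certify performance
on real interactomes or alignments.

## Known limitations and numerical notes

* With 100 random sets the two-sided conservation p-value is discrete with
  floor 1/101; a single null set tying the observed delta doubles the p-value
  past 0.01.  For the planted *variable* column this happens for a small
  fraction of seeds (a null set consisting entirely of W/C-type pairs), so
  end-to-end planted-column recovery is 7/7 for most seeds and 6/7
  occasionally.  Raising the random-set count restores resolution.
* Pipeline problem sizes (300-node background, 100 rewired replicates, 200
  calibration profiles, 2 500 walks per commute-time comparison) are the
  package's reference desk-scale conditions; all scale linearly via the
  config.
* Rewired replicates can disconnect the graph; kernel values are then taken
  on the largest component and unreachable candidate pairs simply drop out of
  the pooled null for that replicate.
* Quantiles are type-7 (linear interpolation); node order is lexicographic
  before any linear algebra; kernels are symmetrised after the spectral
  reconstruction; all stochastic steps take explicit seeds, with replicate
  seeds derived as `seed + index` (mod 2³¹ − 1).
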