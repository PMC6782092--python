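# Methods

This note records the models implemented in `patchnet`, the defaults and
their rationale, what the synthetic cohort generator does and does not
emulate, and the numerical conventions that make every run reproducible.

## Structural mapping

Structures are parsed from PDB text (ATOM records of standard amino acids;
HETATM and waters dropped; alternate locations resolved to the
highest-occupancy conformer, alphabetically on ties). Canonical protein
sequences are aligned globally to each chain's observed sequence
(match +1, mismatch −1, gap open −5, gap extend −0.5, free terminal gaps so
fragments map correctly). A mapping is accepted only when identity over
aligned columns is at least 0.9 — deposited structures frequently renumber
residues, and a loose alignment would silently misplace mutations. The
threshold is configurable; 0.9 tolerates engineered point mutants while
rejecting homolog-level matches. When a mutation maps to several
structures, all placements are kept and the longest mapped structure is
designated primary.

Solvent accessibility uses the Shrake–Rupley algorithm (probe 1.4 Å,
960 sphere points by default, Fibonacci lattice, van der Waals radii by
element with a 1.7 Å fallback). Relative accessibility divides by the
Tien et al. (2013) theoretical maxima — a published, residue-type-complete
reference; the table is a parameter. Classification: interface membership
(any atom within 5 Å of a partner chain) overrides everything; otherwise
RSA ≥ 5 % is surface and the rest is core. Structures of ≤ 50 residues are
skipped for region calls: tiny folds and peptide fragments have unreliable
burial statistics. SASA is computed on the monomer state even for chains
extracted from complexes, so that burial reflects the protein's own fold
and interface residues remain a separate category.

Nonsense and frameshift mutations are mapped positionally but excluded
from chemical-class analyses (they have no alternate residue). Records
whose stated reference amino acid disagrees with the mapped structure
residue are flagged `ref-mismatch` and excluded from structural analyses
rather than silently kept.

## Patch detection

The residue contact graph joins residues whose closest atom pair is
strictly below 5 Å. "Within two contact edges" is the patch relation: an
auxiliary graph on mutated residues links pairs at contact-graph distance
≤ 2; its connected components of size ≥ 2 are patches, singleton components
are singletons. For pairs at distance exactly 2, every intermediate residue
of every shortest path is recorded as a bridge. Patch *size* counts mutated
members only (this matches how recurrently mutated hotspots are usually
counted); the bridge-inclusive total is kept as metadata. Sequence-adjacent
residues participate in contacts by default — they are genuine spatial
neighbours — but a flag removes those edges because they let patches creep
along the backbone.

Patient grouping by patches is iterative and mutually exclusive: rank
features by the number of *remaining* patients carrying them, form a group
from the carriers of the top feature, remove them, and stop when the best
candidate group would fall below the minimum size (default 10). Frequencies
are recomputed on the remainder each round — with static frequencies a
later group could shrink below the threshold mid-sequence. Ties break
lexicographically by feature id, making group order reproducible.

## PCSF reconstruction

Edge costs are `1 − confidence` (a `−log w` transform is available); the
interactome is pre-filtered at confidence ≥ 0.4 and a blocklist of
promiscuous interactors (UBC, APP, ELAVL1, SUMO2, CUL3) and very large
proteins (TTN, MUC16, SYNE1, NEB, MUC19, CCDC168, FSIP2, OBSCN, GPR98)
whose mutation counts track length rather than selection. Prizes are
additive per protein: +1 per significant driver mutation, +0.5 per
non-significant one; non-driver mutations contribute nothing. The hub
penalty enters as an adjusted prize `p′(v) = p(v) − μ·deg(v)`; including a
node with negative `p′` costs `β·|p′|`, which is what makes μ an effective
brake on hub proteins whether they are terminals or connectors.

Both solvers optimize over the same solution space: a candidate is a node
subset realized as the minimum spanning forest of its induced subgraph, one
tree per component, each tree measured from its root (the highest-`p′`
node) and required to stay within the depth bound D. Realizing node sets by
their MSF is the natural convention — given the nodes, any other spanning
topology only adds edge cost — and sharing it between solvers makes their
objectives directly comparable. When an MSF tree breaks the depth bound,
the realization drops the node with the smallest adjusted prize among those
beyond the bound (ties lexicographic) and rebuilds; under very tight hop
bounds (D ≤ 3) a deeper-but-feasible non-MSF tree may exist that this
convention forgoes, a deliberate trade for a well-defined, enumerable
space. At the default D = 6 the bound almost never binds on forests of the
size produced here.

The exact solver enumerates all node subsets (guarded at 12 nodes) and is
the oracle; ties break toward fewer nodes, then the lexicographically
smallest node set. The heuristic seeds with the highest-`p′` terminal,
repeatedly attaches the terminal with the largest positive gain
`β·p′(t) − dist_c(t, F)` along its cheapest path (edge costs plus inclusion
penalties of new negative-`p′` interior nodes), opens a new tree when no
affordable path exists and `β·p′(t) > ω`, prunes subtrees and whole trees
with non-positive net contribution (so a seeded tree that never became
profitable disappears again), and finishes with a deterministic local
improvement: re-realize the node set as its MSF and drop Steiner nodes
while the objective improves. There is no randomness anywhere; identical
inputs give identical forests. Patient networks merge the node and edge
sets of the μ = 0.005 and μ = 0.01 solutions, terminal roles winning over
Steiner on shared nodes.

Prize scaling and the μ adjustment are applied in a fixed order — the hub
penalty acts on the raw prize before β scales it — so that μ has the same
meaning at every β.

## Stratification

Pathway over-representation uses the hypergeometric upper tail with the
filtered interactome as universe (the networks are drawn from it, so it is
the correct reference population). The enrichment score is the
observed/expected overlap ratio — the standard enrichment ratio of
over-representation analysis. Benjamini–Hochberg correction runs per
patient across tested pathways; pathways whose names match a blocklist
(defaults: "infection", "cancer", "addiction") are removed *before*
testing so they never consume FDR budget. The ES matrix holds the score
where q < 0.1 and zero elsewhere; all-zero patient columns are excluded
from clustering and reported, mirroring the attrition a real cohort suffers
between reconstruction and enrichment.

NMF minimizes Frobenius error by multiplicative updates from a seeded
random initialization (no network regularizer). Consensus clustering
repeats NMF on 80 % patient subsamples (default 100 iterations), assigns
each sampled patient to its argmax component, accumulates
co-cluster/co-sample ratios, and cuts the average-linkage dendrogram of
(1 − consensus) into k groups. Only patients are subsampled, not pathways.
k defaults to 5 in the cluster configuration but every entry point takes it
as a parameter (the bundled pipeline uses the number of planted groups);
there is no automatic model selection.

Survival uses the Kaplan–Meier product-limit estimator and the k-sample
log-rank test (df = k − 1). Patch-based survival comparisons exclude
patients left ungrouped by the mutually exclusive grouping. Signature
patches per group come from the hypergeometric upper tail over
(patch, group) pairs with BH correction across all pairs at q < 0.1.

## Drug linkage

A cell line connects to a patch when it shares at least one member
mutation site (protein, position); the justifying sites are recorded on the
edge. Responses given as labels pass through; numeric z-scores of log IC50
binarize at |z| ≥ 1 (sensitive at ≤ −1, resistant at ≥ +1, intermediate
omitted). A drug–target edge survives only when the target protein occurs
in the linked group's merged patient networks. Hypotheses are ranked by
enrichment q ascending, then |z| descending, so the best-supported
(group, patch, line, drug, target) chains come first; every emitted row is
fully evidenced by edges of the typed network.

## Synthetic cohort generator

The generator emulates each external input at desk scale with planted
ground truth. Defaults — the study conditions for all bundled tests —
are: 60 patients in three equal groups, six 80-residue structured driver
proteins each carrying one planted patch of five mutated residues within
12 Å, two singleton mutations per patient (Poisson), a 150-protein
scale-free interactome (target degree exponent 2.5, mean degree ≈ 6),
12 pathway sets of 10–30 proteins, exponential survival with group hazards
1/150, 1/300 and 1/600 per day and 20 % uniform censoring, 20 cell lines,
and one planted (drug, patch, sensitive) association. These sizes keep a
full pipeline run under a few seconds while leaving every statistical
recovery well-powered.

Folds are self-avoiding random walks with 3.8 Å steps (the CA–CA virtual
bond), a 3.6 Å self-avoidance radius mimicking real CA-trace packing, and
a compaction bias (with probability 0.7 the next step is drawn from the
more-compact half of clash-free candidates, measured by radius of
gyration). Each residue carries a CA and one pseudo side-chain atom. The
resulting globules have residue-contact degrees around 4 — contact-rich
enough to plant five-residue patches around a hub, sparse enough that
singletons at graph distance > 2 from all other mutations still fit.

Planted truth is unambiguous by construction: patch members all neighbour a
common contact hub (pairwise distance ≤ 2), patches on the same protein are
kept > 2 edges apart, singletons land on surface positions > 2 edges from
every other mutated residue of the same protein, and every planted site is
mutated in at least one patient. Group members carry at least one mutation
in each of their group's signature patches. The interactome wires each
group's signature proteins through dedicated high-confidence partner
proteins (never directly to each other), and one pathway per group covers
that module — this is what makes group identity recoverable from network
enrichment. Cell lines carry each planted patch with probability 0.4 and
respond to mapped drugs per the effect map, with random labels elsewhere;
mapped drugs target their patch's protein.

What the generator does *not* emulate: sequence evolution, side-chain
chemistry, copy-number or expression data, inter-protein patches on
complexes, measurement noise in drug response, and the long tail of
passenger-only patients. Passing tests therefore demonstrate the
correctness and internal consistency of the algorithms under clean planted
signal, not their power on real cohorts, where mapping coverage, driver
annotation quality and interactome bias dominate.

## Numerical conventions

Determinism throughout: all randomness flows from `numpy` `SeedSequence`
derivations of a single seed; identical configurations produce
byte-identical output files. Tie-breaks are lexicographic everywhere
(feature ids in grouping, node ids in PCSF, patch ids from sorted
components). Contact and interface cutoffs are strict inequalities; the
RSA surface rule is inclusive (≥ 5 %). Fisher's two-sided p sums
hypergeometric probabilities of tables no more probable than the observed
one. The Mann–Whitney comparison uses the exact U distribution for small
untied samples and the tie-corrected normal approximation otherwise.
Degenerate inputs degrade softly: empty prize sets give empty forests,
all-censored survival gives p = 1 with a warning, zero-margin contingency
rows are dropped with a warning.

## Known limitations

The exact PCSF solver is exponential and guarded at 12 nodes; it exists as
an oracle, not a production path. The subset+MSF solution space can forgo
feasible non-MSF trees under hop bounds ≤ 3 (see above). Patch detection
carries no statistical background model — a dense mutated region is a
patch regardless of local mutability. mmCIF structures, homology
modelling and interface prediction from monomers are out of scope;
interfaces require complex structures or supplied annotations.
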