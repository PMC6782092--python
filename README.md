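# patchnet

**3D mutation patches, patient-specific Steiner-forest networks and
network-guided stratification for tumor cohorts.**

Somatic mutation profiles of aggressive tumors such as glioblastoma are
extremely heterogeneous: two patients rarely share the same mutated
positions, which frustrates any attempt to group patients by raw mutation
lists. `patchnet` reduces this heterogeneity in two complementary ways:

1. **In structure space** — mutations from all patients are mapped onto
   protein structures and aggregated into *3D patches*: sets of mutated
   residues that are spatially adjacent on the residue contact graph even
   when they are far apart in sequence. Patients who hit the same patch
   likely perturb the same functional site.
2. **In network space** — each patient's mutated driver proteins seed a
   prize-collecting Steiner forest (PCSF) on a confidence-weighted
   interactome, producing a patient-specific subnetwork. Patients are then
   clustered by the pathways over-represented in their subnetworks, and the
   resulting groups are tested against survival and cell-line drug response.

The package is a library of composable analysis modules plus a synthetic
cohort generator with planted ground truth, so the entire pipeline is
testable without any external downloads.

## The models at the core

**Contact graph and patches.** For a structure, the residue contact graph
`R(v, e)` joins two residues when any atom pair lies closer than 5 Å. Two
mutated residues belong to the same patch when their contact-graph distance
is at most 2 — they touch directly, or exactly one *bridge* residue sits
between them. Patches are the connected components (of size ≥ 2) of this
"within two edges" relation over all mutated residues of the cohort;
unassigned mutated residues are *singletons*. A patch is *inter* if any
member is an interface residue (within 5 Å of a partner chain), else
*intra*. Regions come from relative solvent accessibility (Shrake–Rupley
SASA over the Tien et al. 2013 maxima): RSA ≥ 5 % ⇒ surface, otherwise
core, with interface membership overriding both.

**Patient networks.** On an interactome `G(V, E, w)` with edge costs
`c(e) = 1 − w(e)`, each patient's mutated driver proteins carry prizes
(`+1` per significant mutation, `+0.5` otherwise, additive per protein).
The solver minimizes

```
Σ_{v ∉ F} β·p′(v)⁺  +  Σ_{e ∈ F} c(e)  +  ω·(# trees in F),
p′(v) = p(v) − μ·deg(v)
```

over depth-bounded forests `F` (defaults ω = 10, β = 10, D = 6,
μ ∈ {0.005, 0.01}; edges with confidence < 0.4 and a blocklist of
promiscuous/giant proteins are removed first). The two μ runs are merged
into one network per patient. An exhaustive exact solver doubles as the
test oracle for the deterministic greedy heuristic used at cohort scale.

**Stratification.** Each patient network is scored for pathway
over-representation (hypergeometric test against the filtered-interactome
universe, Benjamini–Hochberg FDR < 0.1, disease-named pathways removed);
the enrichment scores form a pathway × patient matrix that is factorized
(NMF, multiplicative updates) and consensus-clustered (repeated 80 %
patient subsampling) into `k` groups. Groups are compared by Kaplan–Meier /
log-rank, each group's *signature patches* are found by hypergeometric
enrichment, and signature patches are linked through shared mutations to
cell lines, drugs and drug targets into a therapeutic hypothesis network.

## Worked example

```python
from patchnet.synthcohort import SyntheticConfig, generate_cohort
from patchnet.pipeline import run_pipeline

cohort = generate_cohort(SyntheticConfig(seed=7))   # 60 patients, 6 folds
result = run_pipeline(cohort)

print(f"mutations: {len(cohort.mutations)}  "
      f"patches: {len(result.patches)}  singletons: {len(result.singletons)}")
stat, df, p = result.cluster_logrank
print(f"clusters: {result.cluster_labels.value_counts().to_dict()}")
print(f"log-rank: chi2={stat:.2f}, df={df}, p={p:.2e}")
```

prints

```
mutations: 179  patches: 6  singletons: 46
clusters: {'cluster-2': 20, 'cluster-1': 20, 'cluster-3': 20}
log-rank: chi2=16.61, df=2, p=2.47e-04
```

All six planted 5-residue patches are detected exactly (46 of the 179
mutations are dispersed singletons), the three planted patient groups are
recovered perfectly from pathway profiles alone, and the groups — planted
with distinct exponential death hazards — separate strongly in survival.
The top entry of `result.hypotheses` recovers the planted drug link:

```
cluster-2 / G1-1 / CL02 / drug-1 -> sensitive (target G1)
```

i.e. the group whose signature patch lies on protein G1 is connected, via a
cell line sharing a patch mutation, to the drug that was planted as
effective against carriers of that patch.

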