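# Methods

`pharmasieve` implements a combined in-silico / in-vitro ligand-discovery
workflow for aminergic GPCR targets (the dopamine D2 receptor being the
motivating case): 3D pharmacophore screening with exclusion volumes,
enrichment-based model validation, consensus hit triage, and HTRF
competition-binding analysis. This note records the models, conventions and
design choices, so results are interpretable and reproducible.

## Pharmacophore model and matching

A model is a set of labelled feature points `f_k` with kinds from
{PI, HBA, HBD, HC, AI}, centres `c_k` (Å) and tolerance radii `t_k > 0`,
plus exclusion volumes (XVOLs): spheres representing receptor bulk. A
conformer *matches* when there is an injective, kind-compatible assignment
of its perceived ligand features to the model features such that, after
least-squares rigid superposition of the paired points (Kabsch, SVD), every
paired ligand feature lies within its tolerance sphere and **no heavy atom
falls strictly inside any XVOL**. XVOL clash is tested against heavy-atom
centres only (no van der Waals radii) — the simplest reading of exclusion
volume semantics; radius calibration is the model author's job.

Candidate assignments are enumerated by backtracking with sound pairwise
pruning: an assignment is extended only while
`|d_model(i,j) − d_ligand(i,j)| ≤ t_i + t_j` for every assigned pair, a
necessary condition for any rigid superposition to succeed (triangle
inequality). The test suite verifies pass/fail equality with a brute-force
matcher on hundreds of random toy instances.

Ligand-side feature perception (RDKit substructure rules):

- **PI** — protonatable basic nitrogens: aliphatic amines, amidines,
  guanidines; amide/sulfonamide nitrogens, anilines and aromatic N excluded.
- **HBA** — O and sp/sp² N with an available lone pair and no positive
  charge; a PI nitrogen is never additionally counted (mutual exclusion).
- **HBD** — N–H/O–H heteroatoms, again excluding PI nitrogens.
- **AI** — centroid of each aromatic SSSR ring, with the ring normal.
- **HC** — centroid of each connected fragment of ≥ 3 carbon/halogen atoms
  none of which touches a polar atom (N, O, P, S).

Hydrogen-bond features are matched as points on the heteroatom; projected
points / direction cones are an extension hook, not implemented, because
no directional tolerances are defined for the models we emulate. A model
site that accepts *either* donor or acceptor chemistry is encoded as two
optional features sharing a centre inside an XOR group (exactly one must
match).

Matching is alignment-based, so pass/fail and score are invariant under
rigid motion of the conformer (property-tested).

### Fit score

`S = 10·n + 9·(1 − mean_i(d_i/t_i))`, second term clamped to [0, 9], with
`n` the number of paired features and `d_i` the post-alignment distances.
Strictly increasing in `n`, strictly decreasing in each `d_i`. Only the
*ordering* the score induces is load-bearing (hit ranking, cluster
representative selection); the scale is arbitrary. Ties break on the
lexicographically smallest assignment, making screening deterministic.

### Greedy model optimization

`optimize_model` improves a model against labelled actives / inactives /
decoys with moves: shrink one tolerance by δ (default 0.1 Å, floor 0.2 Å),
enlarge one XVOL by δ, add an XVOL (default radius 1.2 Å) at a
false-positive atom hotspot, remove a feature, or mark one optional. A move
is kept only if the enrichment factor does not decrease and sensitivity
stays at or above a floor (default: the input model's sensitivity); an
added XVOL must additionally eliminate at least one inactive or decoy with
no loss of sensitivity. Hotspots are aligned false-positive heavy-atom
positions clear of every aligned true-positive atom, ranked by coverage.
The loop is greedy (best admissible move per iteration) and stops when no
move improves (EF, −FP count) or the move budget (default 50) is spent, so
the returned EF is never below the input's and the EF trace is
non-decreasing.

## Screening metrics

With tp/fp/tn/fn tallied over the full database (N = n_act + n_inact +
n_dec):

    sensitivity = tp / n_act            specificity = tn / (tn + fp)
    accuracy    = (tp + tn) / N         YoA = tp / (tp + fp)
    EF          = YoA / (n_act / N)

YoA is defined as 0 (flagged) for an empty hitlist. The identity
`EF = YoA·N/n_act` holds to machine precision and is property-tested.
Displayed values use decimal half-up rounding (2 dp). On the emulated
68/68/3752 benchmark the count rows reproduce the published sensitivity,
specificity and accuracy for every model and their union, YoA for the
first model and the union, and EF for the first and third models and the
union, exactly at the printed precision. Two published YoA cells (0.30,
0.52) and two EF cells (17.26, 29.57) imply hit totals one larger than the
printed counts (53 and 58 rather than 52 and 57); they are not derivable
from the printed rows under any single rounding convention, and the
package documents rather than chases them. The union row's decoy count
(108) likewise exceeds the sum of the per-model decoy rows (107).

Prospective performance is the hit rate `100·confirmed/tested` (one
decimal, half-up).

## Hit triage

- **Physicochemical filter** — inclusive bounds per descriptor:
  MW 200–600 g/mol, cLogP 1.5–6.0 (Crippen; the estimator is named in
  output metadata), HBA 0–7, HBD 0–3, rotatable bonds 0–18 (non-ring single
  bonds between non-terminal heavy atoms, amide C–N excluded), rings 2–5
  (SSSR), aromatic rings 1–3. Failing bounds are reported by name.
- **PAINS** — the three published substructure families at default
  settings (RDKit `FilterCatalog` PAINS A/B/C); custom SMARTS catalogs can
  be loaded from `SMARTS<TAB>id` files.
- **Consensus categories** — triple (M2 + M4 + M1/M3), the three doubles,
  then singles; the two ligand-screening models are pooled into one M1/M3
  slot because they never co-retrieve a hit in the emulated setting (the
  code still categorizes an M1∩M3 hit, with a warning). Categories
  partition any hit set.
- **Scaffold diversity** — ECFP4 (Morgan radius 2, 2048 bits, 2D) Tanimoto;
  greedy leader clustering at TS ≥ 0.6 (configurable; the source
  workflow prunes "similar scaffolds" without publishing a threshold)
  within each category, keeping each cluster's best-scoring member;
  similarity is never compared across categories; single-model picks are
  capped at 16 per model.
- **Selection for testing** — rank by category priority then fit score;
  exact structural matches in a user-supplied known-actives table (id or
  SMILES; the offline stand-in for literature/target-prediction lookups)
  are excluded. Deterministic.

## HTRF assay analysis

Wells are read at 620 nm (donor) and 665 nm (acceptor); the analysis ratio
is `R = 10⁴·F665/F620` (the 10⁴ scale is a reporting convention; R is
invariant under common rescaling of both channels). Concentrations are
mol/L internally; µM appears only in report tables.

- **DNF** (normalized decrease in fluorescence):
  `Δ_w = mean(R | tracer-only) − R_w`,
  `DNF_i = mean(Δ | compound i) / mean(Δ | control)`, so the control scores
  exactly 1; a compound is called active at DNF ≥ 2. The SD is the
  replicate spread of Δ scaled by the control mean. DNF is invariant under
  any common positive rescaling of all wells. (The published screening
  table lists two entries with DNF 1.68/1.83 under an "active" caption; the
  implemented call follows the stated ≥ 2 rule.)
- **Saturation**: `R(L) = R0 + NS·L + Bmax·L/(KD + L)` by nonlinear least
  squares (scipy `curve_fit`, trust-region with per-parameter scaling —
  KD ~ 1e−9 and Bmax ~ 1e3 otherwise strain the optimizer). Half of the
  specific signal is reached at L = KD.
- **Competition**: four-parameter logistic
  `R(c) = bottom + (top − bottom)/(1 + 10^((log₁₀c − log₁₀IC50)·h))`;
  monotone/flat data are flagged as degenerate.
- **KI**: Cheng–Prusoff, `KI = IC50/(1 + L*/KD)` — the standard correction
  for competitive binding; monotone decreasing in KD (property-tested).
- **Fold difference** vs a reference ligand: `KI_ref/KI`, one decimal below
  100 and two significant figures above; exact rounding ties resolve
  downward (so 11.12/0.32 = 34.75 reports as 34.7). Fold differences are
  computed from unrounded fits.
- **Confidence intervals**: nonparametric percentile bootstrap (default
  1000 resamples, seeded) over case-resampled replicate wells within each
  (compound, concentration) group. Noise-free data give a degenerate CI at
  the estimate.

## Synthetic data generator

The generator replaces the commercial libraries and wet-lab plates with
inputs whose ground truth is known, in the published study's proportions.

- **Reference models M1′–M4′** reproduce the published feature-kind and
  XVOL counts (1 PI + 3 HC + 2 HBA with 60 XVOLs; 1 PI + 3 HC + HBA + HBD
  with 113; 1 PI + superimposed HB pair + AI + HC with 61; 1 PI + HBA +
  HBD + AI + 2 HC with 122). The true model coordinates are proprietary
  and unpublished, so geometry is derived from template ligands — an
  arylpiperazine for the two receptor-structure-style models and a
  phenol/arylpiperidine for the two ligand-style models — by embedding one
  conformer (ETKDG + MMFF, fixed seed) and placing model features on its
  perceived features (tolerance 1.5 Å). XVOLs (radius 1.2 Å) sit on a
  deterministic Fibonacci shell 3.5 Å beyond the farthest template atom,
  emulating receptor bulk without blocking template-sized ligands.
- **Actives** are unique F/Cl/methyl ring-decorated template variants whose
  conformer inherits the template geometry (decoration atoms placed along
  the exocyclic direction), verified against the parent model at
  generation time; the verified conformer ships with the molecule. This
  is why benchmark sensitivity is 1 by construction.
- **Inactives** are the same chemotypes with the basic ring nitrogen
  carbonized: no protonatable nitrogen, hence no PI feature, verified to
  fail the model.
- **Decoys** (default 55 per active → 3740 for 68 actives) are assembled
  from an aryl/linker fragment grammar (amides, esters, ethers,
  sulfonamides, ureas; no basic nitrogen) and accepted only inside their
  parent active's descriptor bins (MW ± 25 g/mol, cLogP ± 1.0, HBD ± 1,
  HBA ± 1, rotatable ± 2) with ECFP4 TS < 0.3 to *every* active — the
  established property-matched decoy convention. Because decoys carry no
  PI, they are rejected topologically and the fixture model's EF on the
  default benchmark equals N/n_act (= 57); screening decoys therefore
  probes the missing-feature path, not XVOL geometry (the optimizer and
  matcher tests probe those separately with geometric instances).
- **Plates** draw wells from the saturation / logistic models above with
  multiplicative Gaussian noise of stated CV (fluorescence-counting
  behaviour), at a fixed 620-nm level so all variation appears in the
  ratio; dilution series are placed around each compound's expected IC50,
  as working concentrations are chosen in practice. Triplicates by
  default; deterministic per seed.

What passing on this synthetic benchmark does **not** show: robustness to
conformer-sampling failure on flexible real actives, decoys that satisfy
the pharmacophore geometrically, tautomer/protonation ambiguity, assay
artifacts other than proportional noise, or plate-position effects. The
generated actives trade physical realism (decoration placement is
idealized, not re-minimized) for exact feature geometry.

## Problem sizes and runtimes

Defaults used by the test suite and `scripts/acceptance.py`: the full
68/68/3740 benchmark with conformer cap 5 for screening (attached
conformers are used when present); 500 random toy instances for oracle
equivalence and 100 model/library pairs for monotonicity; 100 simulated
plates per ground-truth KI in {0.004, 0.32, 1.24, 2.63, 4.31, 11.12} µM at
5 % CV (median relative KI error ≈ 8–9 %, versus a 15 % bound); 20 label
shuffles for the no-enrichment control. The whole suite runs in well under
a minute on one core; scaled-down fixtures (12/12/60) back the faster unit
tests.

## Known limitations

- Conformer generation defaults to 200 per molecule (255 available by
  config), but matching quality on *flexible* external libraries depends on
  that ensemble; the synthetic actives sidestep this by shipping their
  construction conformer.
- The commercial matchers this package replaces use unpublished scoring and
  partial-match ("min features") policies; here all non-optional features
  are required and the fit score is the documented formula. Rank orders,
  not absolute scores, should be compared.
- The greedy optimizer rescreens the labelled sets per candidate move; it
  is intended for benchmark-scale datasets, not hundred-thousand-compound
  libraries.
- The M1∩M3 consensus case never arises in the emulated setting; its
  handling (pool into M1/M3 with a warning) is defined but untested against
  any external ground truth.
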