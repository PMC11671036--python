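# Methods

## Model and procedure

The package operationalizes a simple observation: the conformational state
a structure predictor emits is largely determined by which coevolutionary
subfamily of the MSA it sees. The pipeline therefore (1) restricts the MSA
to well-aligned rows, (2) partitions it into density clusters, (3) turns
each cluster into a prediction-ready single- or multi-chain alignment,
(4) predicts one model per cluster, and (5) maps the models onto a
two-state axis by RMSD against experimentally determined active and
inactive references.

Assumptions worth keeping in mind:

- One model per cluster with few recycles (defaults: 1 model, 3 recycles in
  job manifests) is treated as a sample from the landscape, not a converged
  prediction.
- State assignment presumes the references and the predictions share
  residue numbering; mapping is by configured resseq ranges, not sequence
  alignment.
- The two-reference axis cannot represent intermediate or third states
  except as "excluded"/"ambiguous".

## Clustering parameters

- **Encoding.** 22-symbol one-hot (20 amino acids, `-`, unknown). All
  non-standard residue codes share the unknown slot, keeping the encoding
  total. Squared Euclidean distance = 2 × Hamming distance, which puts
  epsilon on the scale used by the wider MSA-clustering ecosystem.
- **Gap filter.** Rows with *strictly more than* 25% gaps among match
  columns are removed (exactly 25% is kept). Insertions are not alignment
  columns and are ignored by the count. The operation is idempotent.
- **`min_samples`** defaults to 3. The method sources do not pin this
  value; 3 is the smallest value that distinguishes density from pairs and
  is exposed everywhere.
- **Epsilon grid** defaults to 3.0–25.0 in 0.5 steps: wide enough to
  bracket `epsmax` and the confident-classification optimum on alignments
  of a few hundred columns, small enough to scan in seconds.
- **Tie-breaking.** DBSCAN expansion proceeds in ascending point-index
  order (border points join the earliest-seeded reachable cluster, the
  same rule scikit-learn applies); `epsmax` and the state-coverage
  criterion break ties toward the smaller epsilon. All outputs are
  deterministic.

## Assembly

Chain order is fixed (receptor, then partner; copies of one chain are
adjacent), which makes span arithmetic deterministic and assembly
bijective: `split_unpaired` recovers the exact input alignments, including
ids and insertion characters. The merged query row is fully paired even in
unpaired mode because predictors require a complete query; the partner's
own query row is merged into row 0 and not emitted separately. Non-gap
character count is conserved by construction. Serialization uses the
ColabFold complex-A3M dialect (`#len1,len2<TAB>copies1,copies2`).

## Classification

- RMSD uses CA atoms by default (the convention for transmembrane-segment
  comparisons); `backbone` and `all-heavy` subsets are available.
- Superposition is fitted on the selection itself by default. Fitting on
  the whole shared CA set and measuring the selection without refit
  (`fit_on="whole"`) is also implemented: a rigid displacement of a
  segment is invisible to a local fit but visible to a global one, and
  which convention a study intends is often underspecified. Both are
  tested; the default is the local fit.
- Exact RMSD ties yield `ambiguous` rather than an arbitrary state.
- The three rules and their boundary semantics: `argmin_excl3` excludes
  when both RMSDs exceed 3.0 Å (3.0 itself is kept); `thresh35` requires
  strictly less than 3.5 Å; `gcgr54` accepts min RMSD ≤ 5.4 Å — the
  separation of the motivating reference pair, recomputable via
  `reference_gap_rmsd` — gated on mean plDDT strictly greater than 70.
- Percentages in landscape summaries are taken over all calls (including
  excluded and ambiguous) so the four states always sum to 100%; raw
  counts are emitted alongside. Top-fraction ranking takes
  `ceil(fraction × n)` calls, ties broken by model id.

## Synthetic data generators

**Planted-family MSAs.** Each family owns a disjoint block of signature
columns carrying a family-specific residue; all other columns start from a
shared background consensus and are independently mutated (rate μ) and
gapped (rate γ) per row. Expected one-hot squared distance is
2 × E[Hamming]:

- within family: `2 (L − s) p_diff`, where
  `p_diff = 1 − γ² − (1−γ)² (1 − p_res)` and
  `p_res = 2μ(1−μ) + μ²·18/19`;
- between families: `2 [ 2s (1 − (1−γ)μ/19) + (L − 2s) p_diff ]`.

At μ = γ = 0 this gives within-distance 0 and between squared distance
`4s`. `suggested_epsilon()` returns the root-mean of the two regimes and
is what planted-recovery tests and pipelines use. These closed forms are
verified against brute-force distance computation in the test suite.

**Two-state structures.** CA-only ideal-helix-like traces (2.3 Å radius,
1.5 Å rise, 100° turn); the last 30% of residues (the analogue of an
activation swing of an intracellular helix segment) is rigidly translated
between the inactive and active templates. Two gap conventions are
implemented exactly:

- fit on the undisplaced core, measure everything: RMSD = `d·√f` in closed
  form (`d` displacement, `f` displaced fraction);
- full Kabsch fit on the selection: smaller than `d·√f` because the
  optimal rotation absorbs part of a rigid segment shift. When a target
  Kabsch gap is requested (default 5.0 Å), `d` is calibrated by Brent root
  finding; the bracket is valid because the Kabsch gap is bounded above by
  `d·√f`.

A decoy template (segment displaced off the active–inactive axis by
1.5 × d) sits more than 3 Å from both references and exercises the
exclusion branches. The state sampler adds i.i.d. Gaussian coordinate
noise; its raw squared RMSD to its own template follows σ²χ²₍₃ₙ₎/n, which
the tests check by Monte Carlo.

**What the generators do not emulate.** Real MSAs have phylogenetic
correlation, indel structure, and family sizes spanning orders of
magnitude; real predictors have confidence–accuracy correlations and
failure modes the mock's rule tables merely stipulate. Passing tests
demonstrate that the pipeline machinery is correct and deterministic — not
that a neural predictor will reproduce planted landscapes on real
proteins.

## Mock predictor

Rule tables map cluster labels (or the family tags embedded in generated
row ids) to a planted state and Normal distributions for plDDT and ipTM.
The first chain of a job receives the planted state's template; partner
chains use the inactive template of their own length (partners are not the
metamorphic component). Per-job randomness derives from
(predictor seed, settings seed, cluster label or a CRC of row ids), so
outputs are bit-reproducible — repeated runs produce byte-identical PDB
files. plDDT is stored in the PDB B-factor column; ipTM travels in a
`scores.json` sidecar, matching real predictor output layouts so the
analysis stage is adapter-agnostic.

Scenario rule tables plant 75/18/7 (agonist), 65/29/6 (antagonist), or
50/50 (apo) active/inactive/decoy fractions, plus a high-confidence pool
of `ceil(0.1 n)` clusters whose composition (e.g. 19 active + 4 inactive
of 23) dominates every top-10% ranking. These proportions are recognizable
receptor-landscape test vectors; they are generator inputs, not claims
about predictor behavior.

## Scale of the shipped computations

Tests and the acceptance script run planted scenarios at 100 and 230
clusters (4 rows per family, alignments of 160–290 columns), sizes at
which clustering, assembly, mock prediction, and classification complete
in seconds on one CPU while exercising every code path, including the
exact 23-model top-10% pool.

## Known limitations

- Paired-mode assembly takes an explicit pairing list; taxonomy-based
  ortholog pairing is out of scope.
- The ColabFold adapter is a thin subprocess wrapper and is exercised only
  for its unavailable-binary error path; GPU inference is deliberately
  outside the package.
- PDB only (no mmCIF); first MODEL only; altlocs resolved by highest
  occupancy then alphabetical.
- `subsample_maxmsa` implements depth limiting as a two-part random split;
  the profile-based subsampling of full prediction stacks is not
  reproduced. Both returned parts carry the query as row 0 so each is a
  valid alignment; disjointness refers to non-query rows.
- Residue-range selections ship as templates; choosing biologically
  meaningful segments (e.g. the intracellular portions of TM5–TM6 for a
  GPCR) remains the user's responsibility.
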