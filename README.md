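# confland

Conformational-landscape prediction pipelines for metamorphic proteins and
their complexes: cluster a protein's multiple sequence alignment (MSA) into
coevolutionary families, assemble per-cluster multi-chain alignments, route
them through a pluggable structure predictor, and classify the predicted
models into conformational states.

## The problem

Deep-learning structure predictors fed a full MSA collapse multistate
proteins — GPCRs switching between active and inactive conformations,
proteins that refold on dimerization — onto a single conformation.
Subsampling or clustering the MSA restores the hidden states: DBSCAN over
one-hot encoded sequences isolates coevolutionary families, and predicting
each family separately samples the conformational landscape. For
receptor–ligand complexes, each receptor cluster is merged with the full
ligand MSA as an *unpaired* alignment with diagonal padding (each chain's
rows occupy their own column span, gaps elsewhere); for monomer/dimer
switchers, the cluster's sequences are duplicated per protein copy. The
resulting models are assigned to states by segment RMSD against active and
inactive reference structures, and confidence scores (mean plDDT for
stability, ipTM for interface quality) rank the landscape.

## Method summary

- **Encoding and clustering.** Sequences are one-hot encoded over a
  22-letter alphabet (20 amino acids, gap, unknown), so the squared
  Euclidean distance between rows is twice their Hamming distance. Rows
  with more than 25% gaps in match columns are removed first. DBSCAN (own
  implementation, deterministic tie-breaking, validated against
  scikit-learn) emits clusters with the query prepended to each.
- **Epsilon selection.** `scan_epsilon` reports cluster counts across a
  grid and `epsmax`, the epsilon maximizing the number of clusters.
  `select_epsilon_by_state_coverage` instead maximizes the number of
  clusters confidently classified into a state (RMSD within the reference
  gap, mean plDDT > 70), the criterion for raising epsilon when `epsmax`
  clusters are too shallow to predict confidently.
- **Assembly.** `pad_concat_unpaired`, `pair_concat`, and
  `duplicate_homooligomer` build prediction-ready complex alignments;
  assembly is bijective (splitting at chain boundaries recovers the inputs
  exactly) and serializes to the ColabFold `#lengths<TAB>copies` A3M dialect.
- **Classification.** Models are superposed on a configured residue
  selection (CA atoms by default) with Kabsch's algorithm and classified by
  the lowest reference RMSD under one of three rules: a 3.0 Å exclusion
  radius, a strict 3.5 Å per-state threshold, or a reference-gap radius
  (5.4 Å for the GPCR pair that motivates it) gated on mean plDDT > 70.
  Landscapes are summarized as state counts/percentages, overall and for
  the top confidence fraction (default top 10% by ipTM or plDDT).

Real structure prediction (AlphaFold-Multimer / ColabFold) stays behind the
`Predictor` contract; a deterministic `MockPredictor` driven by planted
rule tables makes the entire pipeline testable on a laptop.

## Worked example

```python
from confland import (TwoStateMsaSpec, make_two_state_msa, filter_by_gap_fraction,
                      cluster_msa, run_mock_scenario)

spec = TwoStateMsaSpec(n_families=2, rows_per_family=12, match_length=60,
                       family_signature_columns=5, background_mutation_rate=0.0, seed=7)
msa, labels = make_two_state_msa(spec)
print("rows:", msa.n_rows, "suggested epsilon:", round(spec.suggested_epsilon(), 3))
clusters = cluster_msa(filter_by_gap_fraction(msa), spec.suggested_epsilon(), min_samples=3)
print("clusters:", [(c.label, c.size) for c in clusters])

result = run_mock_scenario("agonist", n_clusters=100, seed=1)
print(result.summary)
print("top-10% by ipTM:", {s: result.top_count(s) for s in ("active", "inactive")})
```

prints

```
rows: 25 suggested epsilon: 3.162
clusters: [(0, 12), (1, 12)]
           count  percent
state
active        75     75.0
inactive      18     18.0
ambiguous      0      0.0
excluded       7      7.0
top-10% by ipTM: {'active': 8, 'inactive': 2}
```

The two planted sequence families are recovered as two clusters of 12. The
agonist scenario plants 75/18/7 active/inactive/decoy clusters; the full
cluster → assemble → predict → classify → summarize pipeline reproduces
those fractions exactly (decoys are excluded by the 3 Å rule), and the
top-10% confidence pool is dominated by the active state, as an agonist's
conformational selectivity should be.

A command-line interface mirrors the library:

```bash
confland msa filter --max-gap 0.25 in.a3m filtered.a3m
confland cluster run --eps 13 --min-samples 3 filtered.a3m clusters/
confland assemble --partner ligand.a3m clusters/ jobs/
confland predict --backend mock --rules rules.yaml --seed 1 jobs/ models/
confland classify --rule argmin_excl3 --ref-active a.pdb --ref-inactive i.pdb \
    --selection sel.yaml models/ landscape/
confland landscape --top-fraction 0.1 --metric iptm landscape/landscape.csv
```

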