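"""End-to-end conformational-landscape pipelines on generated data.

This module wires the stages together — generate or load a receptor
alignment, gap-filter, cluster, assemble per-cluster complex alignments,
predict each job, classify against the two-state references, rank and
summarize — and is what the scenario tests and the acceptance script run.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import pandas as pd

from .assembly import duplicate_homooligomer, pad_concat_unpaired
from .clustering import SequenceCluster, cluster_msa
from .errors import ArgumentError
from .fixtures import (
    MockRuleTable,
    ReferencePair,
    TwoStateMsaSpec,
    TwoStateStructureSpec,
    make_mock_rules,
    make_two_state_msa,
)
from .msa import Msa, filter_by_gap_fraction
from .predictor import MockPredictor, Predictor, PredictorSettings
from .structure import (
    StateCall,
    classify_state,
    landscape_summary,
    rank_top_fraction,
    rmsd_to_references,
)


@dataclass
class ScenarioResult:
    """Everything a scenario run produces, for inspection and assertions."""

    clusters: list[SequenceCluster]
    rules: MockRuleTable
    references: ReferencePair
    calls: list[StateCall]
    summary: pd.DataFrame
    top_calls: list[StateCall]
    top_summary: pd.DataFrame
    planted_states: dict[str, str] = field(default_factory=dict)

    def percent(self, state: str) -> float:
        return float(self.summary.loc[state, "percent"])

    def top_count(self, state: str) -> int:
        return int(self.top_summary.loc[state, "count"])


def classify_predictions(
    results: Sequence,
    references: ReferencePair,
    rule: str,
    fit_on: Literal["selection", "whole"] = "selection",
) -> list[StateCall]:
    """Classify a batch of prediction results against a reference pair.

    The selection is the reference pair's own (receptor chain, all CA); for
    multimeric models only the first chain — the metamorphic receptor — is
    measured.
    """
    calls = []
    for res in results:
        rmsds = rmsd_to_references(
            res.model,
            references.ref_active,
            references.ref_inactive,
            references.selection,
            fit_on=fit_on,
        )
        calls.append(
            classify_state(
                rmsds,
                (res.mean_plddt, res.iptm),
                rule,
                model_id=res.model.model_id,
            )
        )
    return calls


def run_mock_scenario(
    scenario: Literal["agonist", "antagonist", "apo"],
    n_clusters: int = 100,
    rows_per_family: int = 4,
    seed: int = 0,
    rule: str = "argmin_excl3",
    top_fraction: float = 0.10,
    metric: Literal["plddt", "iptm"] = "iptm",
    partner_mode: Literal["ligand", "homodimer"] = "ligand",
    top_pool: tuple[int, int] | None = None,
    receptor_length: int | None = None,
) -> ScenarioResult:
    """Run the full pipeline on a planted ligand scenario with the mock.

    A planted-family receptor alignment with ``n_clusters`` families is
    generated (zero background mutation, so density clustering recovers the
    families exactly), each cluster is merged with a small ligand alignment
    (or duplicated into a homodimer), the mock predictor emits the planted
    state per cluster, and the calls are classified and summarized.
    """
    length = receptor_length or max(160, n_clusters + 60)
    msa_spec = TwoStateMsaSpec(
        n_families=n_clusters,
        rows_per_family=rows_per_family,
        match_length=length,
        family_signature_columns=1,
        background_mutation_rate=0.0,
        gap_rate=0.0,
        seed=seed,
    )
    receptor, _labels = make_two_state_msa(msa_spec)
    receptor = filter_by_gap_fraction(receptor)
    clusters = cluster_msa(
        receptor, msa_spec.suggested_epsilon(), min_samples=min(3, rows_per_family)
    )
    if len(clusters) != n_clusters:
        raise ArgumentError(
            f"planted clustering degenerate: {len(clusters)} != {n_clusters}"
        )

    tags = sorted(
        {
            rid.split("_", 1)[0]
            for cluster in clusters
            for rid, _ in cluster.members.rows[1:]
        }
    )
    rules = make_mock_rules(tags, scenario, top_pool=top_pool)

    structure_spec = TwoStateStructureSpec(n_residues=receptor.match_length)
    mock = MockPredictor(rules, structure_spec, seed=seed)
    settings = PredictorSettings(seed=seed)

    if partner_mode == "ligand":
        ligand_spec = TwoStateMsaSpec(
            n_families=1,
            rows_per_family=6,
            match_length=40,
            family_signature_columns=1,
            background_mutation_rate=0.05,
            gap_rate=0.0,
            seed=seed + 1,
        )
        ligand_raw, _ = make_two_state_msa(ligand_spec)
        # rename rows so ligand ids can never collide with receptor ids
        ligand = Msa(
            (("ligand", ligand_raw.query_seq),)
            + tuple(
                (f"lig{i:03d}", seq)
                for i, (_rid, seq) in enumerate(ligand_raw.rows[1:])
            )
        )
        jobs = [pad_concat_unpaired(c, ligand) for c in clusters]
    else:
        jobs = [duplicate_homooligomer(c, 2) for c in clusters]

    results = [mock.predict(job, settings) for job in jobs]
    references = mock.references_for(receptor.match_length)
    calls = classify_predictions(results, references, rule)
    summary = landscape_summary(calls)
    top_calls = rank_top_fraction(calls, metric, top_fraction)
    top_summary = landscape_summary(top_calls)

    planted = {
        tag: rules.planted_state(tag) for tag in tags
    }
    return ScenarioResult(
        clusters=clusters,
        rules=rules,
        references=references,
        calls=calls,
        summary=summary,
        top_calls=top_calls,
        top_summary=top_summary,
        planted_states=planted,
    )
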