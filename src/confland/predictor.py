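"""The structure-predictor contract, a deterministic mock, and an adapter.

The pipeline never depends on a particular structure predictor: anything
satisfying :class:`Predictor` — given a complex alignment, return one chain
per chain copy with per-residue plDDT (and complex ipTM for multimers) —
can drive the landscape analysis. :class:`MockPredictor` is the test
double: it emits fixture geometry for the conformational state a rule table
plants for each cluster, with seeded coordinate noise and seeded confidence
scores, and is bit-reproducible. :class:`ColabFoldPredictor` is a thin
subprocess adapter for a locally installed ColabFold; it is exercised only
when that binary exists.
"""

from __future__ import annotations

import dataclasses
import json
import shutil
import string
import subprocess
import tempfile
from abc import ABC, abstractmethod
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import yaml

from .assembly import ComplexMsa, write_complex_a3m
from .errors import ArgumentError, PredictionError, PredictorUnavailableError
from .fixtures import (
    MockRule,
    MockRuleTable,
    ReferencePair,
    TwoStateStructureSpec,
    make_two_state_structures,
    stable_job_key,
)
from .msa import match_columns
from .structure import Chain, Residue, StructureModel


@dataclass(frozen=True)
class PredictorSettings:
    num_models: int = 1
    num_recycles: int = 3
    seed: int = 0


@dataclass(frozen=True)
class PredictionResult:
    """One predicted structure with its confidence scores.

    ``mean_plddt`` always equals the mean of the model's per-residue plDDT;
    ``iptm`` is present exactly when the job has more than one chain copy.
    """

    model: StructureModel
    mean_plddt: float
    iptm: float | None
    source_cluster: int | None


class Predictor(ABC):
    """Contract: map a complex alignment to a scored structure."""

    @abstractmethod
    def predict(
        self, job: ComplexMsa, settings: PredictorSettings | None = None
    ) -> PredictionResult:
        """Predict one model for ``job``.

        Implementations must return one chain per chain copy, with as many
        residues per chain as the chain query's match length, per-residue
        plDDT in [0, 100], and ipTM in [0, 1] for multimeric jobs. Failures
        surface as :class:`PredictionError`, never as a silent skip.
        """


class MockPredictor(Predictor):
    """Deterministic test double standing in for a neural predictor.

    A rule table assigns each cluster a conformational state and confidence
    distributions. The first chain (the metamorphic receptor) is emitted as
    the planted state's fixture template plus Gaussian coordinate noise;
    partner chains use the inactive template of their own length. Reference
    pairs are built lazily per chain length from a shared structure spec and
    cached, so downstream analysis can use ``references_for`` to obtain the
    exact references the mock sampled from.
    """

    def __init__(
        self,
        rules: MockRuleTable,
        structure_spec: TwoStateStructureSpec | None = None,
        seed: int = 0,
    ) -> None:
        self.rules = rules
        self.structure_spec = structure_spec or TwoStateStructureSpec()
        self.seed = int(seed) & 0x7FFFFFFF
        self._cache: dict[int, ReferencePair] = {}

    def references_for(self, n_residues: int) -> ReferencePair:
        if n_residues not in self._cache:
            self._cache[n_residues] = make_two_state_structures(
                replace(self.structure_spec, n_residues=n_residues)
            )
        return self._cache[n_residues]

    def predict(
        self, job: ComplexMsa, settings: PredictorSettings | None = None
    ) -> PredictionResult:
        settings = settings or PredictorSettings()
        row_ids = [rid for rid, _ in job.rows]
        rule = self.rules.resolve(job.label, row_ids)
        key = job.label if job.label is not None else stable_job_key(row_ids)
        rng = np.random.default_rng(
            np.random.SeedSequence([self.seed, settings.seed & 0x7FFFFFFF, key])
        )

        chains = []
        chain_letters = string.ascii_uppercase
        chain_index = 0
        for ci, spec in enumerate(job.chain_specs):
            length = spec.match_length
            pair = self.references_for(length)
            state = rule.state if ci == 0 else "inactive"
            template = pair.template_coords(state)
            for _copy in range(spec.copies):
                coords = template + rng.normal(
                    0.0, self.structure_spec.noise_sigma, size=(length, 3)
                )
                plddt = np.clip(
                    rng.normal(rule.plddt[0], rule.plddt[1], size=length),
                    0.0,
                    100.0,
                )
                residues = tuple(
                    Residue(
                        i + 1,
                        "ALA",
                        (
                            dataclasses.replace(
                                pair.ref_inactive.chains[0].residues[i].atoms[0],
                                xyz=tuple(float(v) for v in coords[i]),
                            ),
                        ),
                        float(plddt[i]),
                    )
                    for i in range(length)
                )
                chains.append(Chain(chain_letters[chain_index], residues))
                chain_index += 1
        model = StructureModel(
            tuple(chains), model_id=f"cluster_{key:03d}" if job.label is not None else f"job_{key}"
        )
        iptm = None
        if job.n_chain_copies > 1:
            iptm = float(np.clip(rng.normal(rule.iptm[0], rule.iptm[1]), 0.0, 1.0))
        return PredictionResult(model, model.mean_plddt, iptm, job.label)


class ColabFoldPredictor(Predictor):
    """Subprocess adapter for a locally installed ``colabfold_batch``.

    GPU inference is deliberately outside this package; the adapter only
    hands the serialized complex alignment to the external tool. It raises
    :class:`PredictorUnavailableError` when the binary is absent.
    """

    def __init__(self, executable: str = "colabfold_batch") -> None:
        self.executable = executable

    def predict(
        self, job: ComplexMsa, settings: PredictorSettings | None = None
    ) -> PredictionResult:
        settings = settings or PredictorSettings()
        if shutil.which(self.executable) is None:
            raise PredictorUnavailableError(
                f"{self.executable!r} not found on PATH"
            )
        from .structure import read_structure  # local import to keep startup light

        with tempfile.TemporaryDirectory() as tmp:
            tmp_path = Path(tmp)
            a3m = tmp_path / "job.a3m"
            write_complex_a3m(job, a3m)
            cmd = [
                self.executable,
                "--num-models",
                str(settings.num_models),
                "--num-recycle",
                str(settings.num_recycles),
                str(a3m),
                str(tmp_path / "out"),
            ]
            proc = subprocess.run(cmd, capture_output=True, text=True)
            if proc.returncode != 0:
                raise PredictionError(
                    f"{self.executable} failed ({proc.returncode}): {proc.stderr[-500:]}"
                )
            pdbs = sorted((tmp_path / "out").glob("*_rank_001*.pdb"))
            if not pdbs:
                raise PredictionError("predictor produced no ranked model")
            model = read_structure(pdbs[0])
            scores = sorted((tmp_path / "out").glob("*_rank_001*.json"))
            iptm = None
            if scores:
                with scores[0].open() as fh:
                    iptm = json.load(fh).get("iptm")
            return PredictionResult(model, model.mean_plddt, iptm, job.label)


# ---------------------------------------------------------------------------
# rule-table serialization (YAML, for the CLI)


def _rule_from_dict(d: Mapping) -> MockRule:
    return MockRule(
        state=d["state"],
        plddt=tuple(d.get("plddt", (76.0, 2.0))),
        iptm=tuple(d.get("iptm", (0.55, 0.02))),
    )


def load_rules(path: str | Path) -> tuple[MockRuleTable, TwoStateStructureSpec]:
    """Load a mock rule table and structure spec from YAML.

    Schema::

        default: {state: active, plddt: [85, 3], iptm: [0.8, 0.05]}
        by_label: {0: {state: inactive, ...}}
        by_tag: {fam00: {state: active, ...}}
        structure: {n_residues: 80, target_gap: 5.0, noise_sigma: 0.3}
    """
    with Path(path).open() as fh:
        raw = yaml.safe_load(fh) or {}
    table = MockRuleTable(
        by_label={int(k): _rule_from_dict(v) for k, v in (raw.get("by_label") or {}).items()},
        by_tag={str(k): _rule_from_dict(v) for k, v in (raw.get("by_tag") or {}).items()},
        default=_rule_from_dict(raw["default"]) if raw.get("default") else None,
    )
    spec = TwoStateStructureSpec(**(raw.get("structure") or {}))
    return table, spec


def write_scores_sidecar(
    result: PredictionResult, path: str | Path
) -> None:
    """Write the ``scores.json`` sidecar next to an emitted PDB model."""
    with Path(path).open("w") as fh:
        json.dump(
            {
                "mean_plddt": result.mean_plddt,
                "iptm": result.iptm,
                "cluster": result.source_cluster,
            },
            fh,
        )
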