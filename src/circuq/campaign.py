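"""Local campaign orchestration: encode, execute, capture failures, restart.

A campaign turns validation points (or a sensitivity-analysis input space)
into a deterministic list of concrete runs, executes them with failure
capture, persists results incrementally to an append-only delimited journal,
and can resume an interrupted campaign to a final table identical to an
uninterrupted execution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import QOI_NAMES, QoISet
from .sensitivity import InputSpec, lhs_sample

__all__ = [
    "CampaignPoint",
    "RunSpec",
    "CampaignPlan",
    "RunRecord",
    "ResultsTable",
    "plan_campaign",
    "execute",
    "resume",
]


@dataclass(frozen=True)
class CampaignPoint:
    """A labelled input space to sample (SA mode uses a single wide point)."""

    label: str
    specs: tuple

    def input_specs(self) -> list[InputSpec]:
        return [s for s in self.specs if s.classification != "deterministic"]


@dataclass(frozen=True)
class RunSpec:
    run_id: str
    label: str
    inputs: dict
    seed: int


@dataclass(frozen=True)
class CampaignPlan:
    runs: tuple[RunSpec, ...]
    provenance: dict

    def __post_init__(self) -> None:
        ids = [r.run_id for r in self.runs]
        if len(set(ids)) != len(ids):
            raise ValueError("run ids must be unique")

    @property
    def input_names(self) -> tuple[str, ...]:
        names: list[str] = []
        for r in self.runs:
            for k in r.inputs:
                if k not in names:
                    names.append(k)
        return tuple(names)


def _splitmix64(x: int) -> int:
    """One splitmix64 output for counter ``x`` (documented per-run seeding)."""
    z = (x + 0x9E3779B97F4A7C15) & 0xFFFFFFFFFFFFFFFF
    z = ((z ^ (z >> 30)) * 0xBF58476D1CE4E5B9) & 0xFFFFFFFFFFFFFFFF
    z = ((z ^ (z >> 27)) * 0x94D049BB133111EB) & 0xFFFFFFFFFFFFFFFF
    return (z ^ (z >> 31)) & 0x7FFFFFFF


def plan_campaign(points, n_per_point: int, seed: int = 0) -> CampaignPlan:
    """LHS-sample every point and lay out the runs deterministically.

    The plan has ``len(points) * n_per_point`` runs; each run owns a seed
    derived from the campaign seed by a splitmix64 counter.
    """
    if n_per_point < 1:
        raise ValueError("n_per_point must be at least 1")
    points = list(points)
    if not points:
        raise ValueError("no points to plan")
    runs: list[RunSpec] = []
    counter = 0
    for k, point in enumerate(points):
        specs = point.input_specs()
        pt_seed = _splitmix64(seed * 1000003 + k)
        samples = lhs_sample(specs, n_per_point, seed=pt_seed)
        for i, row in enumerate(samples.rows()):
            runs.append(RunSpec(
                run_id=f"{point.label}/{i:04d}",
                label=point.label,
                inputs=row,
                seed=_splitmix64((seed << 20) + counter),
            ))
            counter += 1
    return CampaignPlan(
        runs=tuple(runs),
        provenance={"sampler": "lhs", "seed": seed, "n_per_point": n_per_point,
                    "points": [p.label for p in points]},
    )


@dataclass(frozen=True)
class RunRecord:
    run_id: str
    label: str
    status: str  # "ok" | "failed"
    inputs: dict
    qois: dict | None = None
    error: str = ""


@dataclass
class ResultsTable:
    """One record per planned run: inputs joined with QoIs and status."""

    records: list
    input_names: tuple[str, ...]

    @property
    def n_ok(self) -> int:
        return sum(1 for r in self.records if r.status == "ok")

    @property
    def n_failed(self) -> int:
        return sum(1 for r in self.records if r.status == "failed")

    def frame(self):
        import pandas as pd

        rows = []
        for r in self.records:
            row = {"run_id": r.run_id, "label": r.label, "status": r.status}
            for k in self.input_names:
                row[k] = r.inputs.get(k, np.nan)
            for q in QOI_NAMES:
                row[q] = (r.qois or {}).get(q, np.nan)
            row["error"] = r.error
            rows.append(row)
        return pd.DataFrame(rows)

    def save(self, path) -> None:
        """Canonical tab-separated table, one row per run, full precision."""
        with open(path, "w") as fh:
            fh.write(_header(self.input_names))
            for r in self.records:
                fh.write(_record_line(r, self.input_names))


def _header(input_names) -> str:
    cols = ["run_id", "label", "status", *input_names, *QOI_NAMES, "error"]
    return "\t".join(cols) + "\n"


def _record_line(r: RunRecord, input_names) -> str:
    vals = [r.run_id, r.label, r.status]
    for k in input_names:
        vals.append(repr(float(r.inputs[k])) if k in r.inputs else "")
    for q in QOI_NAMES:
        if r.status == "ok" and q in (r.qois or {}):
            vals.append(repr(float(r.qois[q])))
        else:
            vals.append("")
    vals.append(r.error.replace("\t", " ").replace("\n", " "))
    return "\t".join(vals) + "\n"


def _parse_journal(path, input_names):
    records: dict[str, RunRecord] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        expected = _header(input_names).rstrip("\n").split("\t")
        if header != expected:
            raise ValueError("journal header does not match the plan")
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            row = dict(zip(header, parts))
            inputs = {k: float(row[k]) for k in input_names if row[k] != ""}
            qois = None
            if row["status"] == "ok":
                qois = {q: float(row[q]) for q in QOI_NAMES if row[q] != ""}
            records[row["run_id"]] = RunRecord(
                run_id=row["run_id"], label=row["label"], status=row["status"],
                inputs=inputs, qois=qois, error=row.get("error", ""),
            )
    return records


def _run_one(run: RunSpec, model, retry: int) -> RunRecord:
    last_err = ""
    for _ in range(retry + 1):
        try:
            out = model(run)
        except Exception as exc:  # failure capture, not fatal
            last_err = f"{type(exc).__name__}: {exc}"
            continue
        if isinstance(out, QoISet):
            out = out.as_dict()
        return RunRecord(run.run_id, run.label, "ok", run.inputs, dict(out))
    return RunRecord(run.run_id, run.label, "failed", run.inputs, None, last_err)


def execute(
    plan: CampaignPlan,
    model,
    workers: int = 1,
    retry: int = 0,
    journal_path=None,
    _skip: dict | None = None,
) -> ResultsTable:
    """Attempt every planned run; failures are recorded, never fatal.

    ``model(run_spec)`` returns a :class:`~circuq.model.QoISet` or a mapping
    of QoI name to value.  With ``journal_path`` each finished run is appended
    immediately, so an interrupted campaign can be resumed.  Results are
    reproducible per run because each run owns its seed.
    """
    input_names = plan.input_names
    done: dict[str, RunRecord] = dict(_skip or {})
    fh = None
    if journal_path is not None:
        fh = open(journal_path, "a")
        if fh.tell() == 0:
            fh.write(_header(input_names))
            fh.flush()

    todo = [r for r in plan.runs if r.run_id not in done]
    try:
        if workers <= 1:
            for run in todo:
                rec = _run_one(run, model, retry)
                done[run.run_id] = rec
                if fh is not None:
                    fh.write(_record_line(rec, input_names))
                    fh.flush()
        else:
            from concurrent.futures import ProcessPoolExecutor

            with ProcessPoolExecutor(max_workers=workers) as pool:
                for run, rec in zip(todo, pool.map(
                    _run_one, todo, [model] * len(todo), [retry] * len(todo)
                )):
                    done[run.run_id] = rec
                    if fh is not None:
                        fh.write(_record_line(rec, input_names))
                        fh.flush()
    finally:
        if fh is not None:
            fh.close()

    records = [done[r.run_id] for r in plan.runs if r.run_id in done]
    if len(records) != len(plan.runs):
        raise RuntimeError("not every planned run produced a record")
    return ResultsTable(records=records, input_names=input_names)


def resume(journal_path, plan: CampaignPlan, model, workers: int = 1,
           retry: int = 0) -> ResultsTable:
    """Finish an interrupted campaign from its journal.

    Runs with an ``ok`` record are kept; every other planned run is
    (re)executed and appended.  With a deterministic model the final table is
    identical to an uninterrupted execution.
    """
    existing = _parse_journal(journal_path, plan.input_names)
    plan_ids = {r.run_id for r in plan.runs}
    unknown = set(existing) - plan_ids
    if unknown:
        raise ValueError(f"journal contains runs not in the plan: {sorted(unknown)[:3]}")
    keep = {rid: rec for rid, rec in existing.items() if rec.status == "ok"}
    return execute(plan, model, workers=workers, retry=retry,
                   journal_path=journal_path, _skip=keep)
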