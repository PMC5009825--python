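"""Readers and writers: dataset CSV, model-spec / parameter / fit JSON.

Dataset CSV schema (header required):
    tissue,population,day,mean,sd,n

All floats are serialized with 17 significant digits so that round-trips
preserve values bit-exactly; no locale-dependent formatting.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .fitting import FitResult, KineticsDataset, Series
from .model import ModelSpec, ParameterSet, ProcessSpec

__all__ = [
    "dataset_to_csv", "dataset_from_csv",
    "spec_to_json", "spec_from_json",
    "params_to_json", "params_from_json",
    "fit_result_to_json",
    "config_hash",
]

_FLOAT_FMT = "%.17g"


def dataset_to_csv(data: KineticsDataset, path) -> None:
    rows = []
    for (tissue, population), s in sorted(data.series.items()):
        for j in range(len(s.days)):
            rows.append((tissue, population, s.days[j], s.mean[j], s.sd[j], int(s.n[j])))
    df = pd.DataFrame(rows, columns=["tissue", "population", "day", "mean", "sd", "n"])
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def dataset_from_csv(path) -> KineticsDataset:
    df = pd.read_csv(path, float_precision="round_trip")
    required = {"tissue", "population", "day", "mean", "sd", "n"}
    if not required.issubset(df.columns):
        raise ValueError(f"dataset CSV must have columns {sorted(required)}")
    series = {}
    for (tissue, population), g in df.groupby(["tissue", "population"], sort=True):
        g = g.sort_values("day")
        series[(tissue, population)] = Series(
            days=g["day"].to_numpy(float), mean=g["mean"].to_numpy(float),
            sd=g["sd"].to_numpy(float), n=g["n"].to_numpy(int),
        )
    return KineticsDataset(series=series, provenance=f"file:{path}")


def _spec_dict(spec: ModelSpec) -> dict:
    return {
        "populations": [list(p) for p in spec.populations],
        "processes": [
            {"kind": p.kind,
             "source": list(p.source) if p.source else None,
             "sink": list(p.sink) if p.sink else None,
             "form_kind": p.form_kind,
             "modifier": p.modifier,
             "driver": list(p.driver) if p.driver else None,
             "name": p.name}
            for p in spec.processes
        ],
        "mobility_mode": spec.mobility_mode,
        "g0_reentry": spec.g0_reentry,
        "hierarchy_level": spec.hierarchy_level,
        "balance": [[list(pool), name] for pool, name in spec.balance],
        "uses_forcing": spec.uses_forcing,
        "label": spec.label,
    }


def spec_to_json(spec: ModelSpec, path=None) -> str:
    text = json.dumps(_spec_dict(spec), indent=1)
    if path is not None:
        Path(path).write_text(text)
    return text


def _load_json(source) -> dict:
    if isinstance(source, Path):
        return json.loads(source.read_text())
    if isinstance(source, str) and not source.lstrip().startswith("{"):
        return json.loads(Path(source).read_text())
    return json.loads(source)


def spec_from_json(source) -> ModelSpec:
    d = _load_json(source)
    procs = [
        ProcessSpec(
            kind=p["kind"],
            source=tuple(p["source"]) if p["source"] else None,
            sink=tuple(p["sink"]) if p["sink"] else None,
            form_kind=p["form_kind"], modifier=p["modifier"],
            driver=tuple(p["driver"]) if p["driver"] else None,
            name=p["name"],
        )
        for p in d["processes"]
    ]
    return ModelSpec(
        populations=[tuple(p) for p in d["populations"]],
        processes=procs,
        mobility_mode=d["mobility_mode"],
        g0_reentry=d["g0_reentry"],
        hierarchy_level=d["hierarchy_level"],
        balance=[(tuple(pool), name) for pool, name in d["balance"]],
        uses_forcing=d["uses_forcing"],
        label=d.get("label", ""),
    )


def params_to_json(params: ParameterSet, path=None) -> str:
    text = json.dumps(
        {"values": params.values,
         "bounds": {k: list(v) for k, v in params.bounds.items()}},
        indent=1,
    )
    if path is not None:
        Path(path).write_text(text)
    return text


def params_from_json(source) -> ParameterSet:
    d = _load_json(source)
    return ParameterSet(values=dict(d["values"]),
                        bounds={k: tuple(v) for k, v in d["bounds"].items()})


def fit_result_to_json(res: FitResult, path=None, extra: dict | None = None) -> str:
    doc = {
        "objective": res.objective,
        "seed": res.seed,
        "refined": res.refined,
        "failed": res.failed,
        "message": res.message,
        "series": [
            {"tissue": k[0], "population": k[1], "d": res.d[k], "s": res.s[k],
             "criterion_d_le_s": bool(res.d[k] <= res.s[k])}
            for k in sorted(res.d)
        ],
        "params": res.params.values,
        "history": res.history,
    }
    if extra:
        doc.update(extra)
    text = json.dumps(doc, indent=1)
    if path is not None:
        Path(path).write_text(text)
    return text


def config_hash(obj) -> str:
    """Stable short hash of any JSON-serializable configuration object."""
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        obj = dataclasses.asdict(obj)

    def default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        return str(o)

    text = json.dumps(obj, sort_keys=True, default=default)
    return hashlib.sha256(text.encode()).hexdigest()[:16]
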