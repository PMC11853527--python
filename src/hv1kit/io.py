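"""Canonical file I/O: long-format trace CSV/JSON, mutation tables, and
multi-model PDB ensembles.

The trace schema is one row per sample with the per-trace metadata repeated:
``family_id, trace_id, V_test_mV, V_hold_mV, pH_o, pH_i, C_m_pF, t_s, I_pA``
plus ``t_repol_s`` and ``V_repol_mV`` when a tail is present, so that the
round trip is lossless.
"""

from __future__ import annotations

import json
import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .geometry import StructureEnsemble
from .hotspot import MutationRecord
from .traces import CurrentTrace, TraceFamily

log = logging.getLogger(__name__)

__all__ = [
    "write_trace_family_csv", "read_trace_family_csv",
    "write_trace_family_json", "read_trace_family_json",
    "write_mutations_csv", "read_mutations_csv",
    "write_ensemble_pdb", "read_ensemble_pdb",
    "SchemaError",
]

TRACE_COLUMNS = ["family_id", "trace_id", "V_test_mV", "V_hold_mV",
                 "pH_o", "pH_i", "C_m_pF", "t_s", "I_pA"]
MUTATION_COLUMNS = ["position", "ref_aa", "alt_aa", "source_db", "tissue",
                    "sample_id"]


class SchemaError(ValueError):
    """An input file does not match the canonical schema."""


def _family_frame(family: TraceFamily) -> pd.DataFrame:
    chunks = []
    for i, tr in enumerate(family):
        df = pd.DataFrame({"t_s": tr.t, "I_pA": tr.I})
        df.insert(0, "family_id", family.family_id)
        df.insert(1, "trace_id", tr.label or f"trace{i}")
        df.insert(2, "V_test_mV", tr.V_test)
        df.insert(3, "V_hold_mV", tr.V_hold)
        df.insert(4, "pH_o", tr.pH_o)
        df.insert(5, "pH_i", tr.pH_i)
        df.insert(6, "C_m_pF", tr.C_m)
        df["t_repol_s"] = np.nan if tr.t_repol is None else tr.t_repol
        df["V_repol_mV"] = np.nan if tr.V_repol is None else tr.V_repol
        chunks.append(df)
    return pd.concat(chunks, ignore_index=True)


def write_trace_family_csv(family: TraceFamily, path) -> None:
    _family_frame(family).to_csv(path, index=False)


def _traces_from_frame(df: pd.DataFrame) -> TraceFamily:
    missing = [c for c in TRACE_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"trace table missing column(s): {', '.join(missing)}")
    if df.empty:
        log.warning("empty trace family file")
        return TraceFamily(traces=[], family_id="empty")
    traces = []
    fam = str(df["family_id"].iloc[0])
    for tid, grp in df.groupby("trace_id", sort=False):
        row = grp.iloc[0]
        t_repol = row.get("t_repol_s", np.nan)
        v_repol = row.get("V_repol_mV", np.nan)
        traces.append(CurrentTrace(
            t=grp["t_s"].to_numpy(), I=grp["I_pA"].to_numpy(),
            V_test=float(row["V_test_mV"]), V_hold=float(row["V_hold_mV"]),
            pH_o=float(row["pH_o"]), pH_i=float(row["pH_i"]),
            C_m=float(row["C_m_pF"]), label=str(tid),
            t_repol=None if pd.isna(t_repol) else float(t_repol),
            V_repol=None if pd.isna(v_repol) else float(v_repol)))
    return TraceFamily(traces=traces, family_id=fam)


def read_trace_family_csv(path) -> TraceFamily:
    return _traces_from_frame(pd.read_csv(path))


def write_trace_family_json(family: TraceFamily, path) -> None:
    payload = {"family_id": family.family_id, "traces": []}
    for i, tr in enumerate(family):
        payload["traces"].append({
            "trace_id": tr.label or f"trace{i}",
            "V_test_mV": tr.V_test, "V_hold_mV": tr.V_hold,
            "pH_o": tr.pH_o, "pH_i": tr.pH_i, "C_m_pF": tr.C_m,
            "t_repol_s": tr.t_repol, "V_repol_mV": tr.V_repol,
            "t_s": tr.t.tolist(), "I_pA": tr.I.tolist()})
    Path(path).write_text(json.dumps(payload))


def read_trace_family_json(path) -> TraceFamily:
    payload = json.loads(Path(path).read_text())
    if "traces" not in payload:
        raise SchemaError("trace JSON missing 'traces'")
    traces = [CurrentTrace(
        t=np.asarray(tr["t_s"]), I=np.asarray(tr["I_pA"]),
        V_test=tr["V_test_mV"], V_hold=tr["V_hold_mV"], pH_o=tr["pH_o"],
        pH_i=tr["pH_i"], C_m=tr["C_m_pF"], label=tr["trace_id"],
        t_repol=tr.get("t_repol_s"), V_repol=tr.get("V_repol_mV"))
        for tr in payload["traces"]]
    if not traces:
        log.warning("empty trace family file")
    return TraceFamily(traces=traces, family_id=payload.get("family_id", "family"))


def write_mutations_csv(records: list[MutationRecord], path) -> None:
    pd.DataFrame([{c: getattr(r, c) for c in MUTATION_COLUMNS}
                  for r in records]).to_csv(path, index=False)


def read_mutations_csv(path) -> list[MutationRecord]:
    df = pd.read_csv(path, dtype={"sample_id": str}, keep_default_na=False)
    missing = [c for c in MUTATION_COLUMNS[:3] if c not in df.columns]
    if missing:
        raise SchemaError(f"mutation table missing column(s): {', '.join(missing)}")
    return [MutationRecord(position=int(r["position"]), ref_aa=str(r["ref_aa"]),
                           alt_aa=str(r["alt_aa"]),
                           source_db=str(r.get("source_db", "")),
                           tissue=str(r.get("tissue", "")),
                           sample_id=str(r.get("sample_id", "")))
            for _, r in df.iterrows()]


def write_ensemble_pdb(ensemble: StructureEnsemble, path) -> None:
    """Write an ensemble as a multi-model PDB (one MODEL per frame)."""
    import MDAnalysis as mda

    n = ensemble.n_atoms
    u = mda.Universe.empty(n, n_residues=n, atom_resindex=np.arange(n),
                           trajectory=True)
    u.add_TopologyAttr("names", ensemble.names)
    u.add_TopologyAttr("resnames", ensemble.resnames)
    u.add_TopologyAttr("resids", ensemble.resids)
    from MDAnalysis.coordinates.memory import MemoryReader
    u.load_new(np.ascontiguousarray(ensemble.coords, dtype=np.float32),
               format=MemoryReader)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        with mda.Writer(str(path), n_atoms=n, multiframe=True) as w:
            for _ in u.trajectory:
                w.write(u.atoms)


def read_ensemble_pdb(path, label: str = "") -> StructureEnsemble:
    """Read a multi-model PDB into a StructureEnsemble."""
    import MDAnalysis as mda

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe(str(path))
        coords = np.array([u.atoms.positions.copy() for _ in u.trajectory])
    return StructureEnsemble(names=list(u.atoms.names),
                             resnames=list(u.atoms.resnames),
                             resids=[int(r) for r in u.atoms.resids],
                             coords=coords, label=label or Path(path).stem)
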