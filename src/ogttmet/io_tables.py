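"""Readers and writers for every table the pipeline touches.

Canonical interchange is long ("tidy") UTF-8 TSV; CSV is accepted by
extension.  Missing intensities are encoded as empty fields, never 0 —
zero is a legal peak height and the presence filter needs true
missingness.  Networks go to GraphML 1.0 via networkx; model reports to
JSON.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass

import numpy as np
import pandas as pd
import networkx as nx

PHASES = ("pre", "post")

PANEL_COLUMNS = ["subject_id", "phase", "time_min", "metabolite_id", "intensity"]
SUBJECT_COLUMNS = ["subject_id", "phase", "time_min", "glucose_mgdl", "insulin_uUml"]


class TableFormatError(ValueError):
    """A file violates the declared schema or a type invariant."""


def _delimiter(path: str, delimiter: str | None) -> str:
    if delimiter is not None:
        return delimiter
    return "," if str(path).lower().endswith(".csv") else "\t"


@dataclass
class Fingerprint:
    """Binary chemical fingerprint for one metabolite."""

    metabolite_id: str
    bits: np.ndarray  # bool vector

    @property
    def n_bits(self) -> int:
        return int(self.bits.size)

    @property
    def on_bits(self) -> frozenset:
        return frozenset(int(i) for i in np.flatnonzero(self.bits))

    def __eq__(self, other):
        return (isinstance(other, Fingerprint)
                and self.metabolite_id == other.metabolite_id
                and self.bits.size == other.bits.size
                and bool(np.array_equal(self.bits, other.bits)))


def read_panel(path: str, schedule, delimiter: str | None = None) -> pd.DataFrame:
    """Read and validate a long-form intensity panel.

    Enforces: declared header, phase in {pre, post}, time_min in the
    declared schedule, non-negative intensity (empty = missing), and
    unique (subject, phase, time, metabolite) keys.  Errors name the
    offending line (1-based, counting the header) and the violated rule.
    """
    delim = _delimiter(path, delimiter)
    df = pd.read_csv(path, sep=delim, dtype={"subject_id": str, "metabolite_id": str},
                     comment="#")
    if list(df.columns) != PANEL_COLUMNS:
        raise TableFormatError(
            f"{path}: header {list(df.columns)} does not match {PANEL_COLUMNS}")
    schedule = set(int(t) for t in schedule)
    bad_phase = ~df["phase"].isin(PHASES)
    if bad_phase.any():
        line = int(df.index[bad_phase][0]) + 2
        raise TableFormatError(f"{path}:{line}: phase must be one of {PHASES}")
    bad_time = ~df["time_min"].isin(schedule)
    if bad_time.any():
        line = int(df.index[bad_time][0]) + 2
        raise TableFormatError(f"{path}:{line}: time_min not in schedule {sorted(schedule)}")
    neg = df["intensity"].notna() & (df["intensity"] < 0)
    if neg.any():
        line = int(df.index[neg][0]) + 2
        raise TableFormatError(f"{path}:{line}: negative intensity (peak heights are >= 0)")
    key = ["subject_id", "phase", "time_min", "metabolite_id"]
    dup = df.duplicated(subset=key, keep=False)
    if dup.any():
        first = df.loc[dup, key].iloc[0].tolist()
        raise TableFormatError(f"{path}: duplicate key {tuple(first)}")
    df["time_min"] = df["time_min"].astype(int)
    return df


def write_panel(panel: pd.DataFrame, path: str, provenance: dict | None = None) -> None:
    _write_tsv(panel[PANEL_COLUMNS], path, provenance)


def read_subjects(path: str, delimiter: str | None = None) -> pd.DataFrame:
    delim = _delimiter(path, delimiter)
    df = pd.read_csv(path, sep=delim, dtype={"subject_id": str}, comment="#")
    if list(df.columns)[:5] != SUBJECT_COLUMNS:
        raise TableFormatError(
            f"{path}: header {list(df.columns)} does not start with {SUBJECT_COLUMNS}")
    if (df["glucose_mgdl"] <= 0).any() or (df["insulin_uUml"] <= 0).any():
        raise TableFormatError(f"{path}: glucose and insulin must be > 0")
    for (s, ph), grp in df.groupby(["subject_id", "phase"]):
        if 0 not in set(grp["time_min"]):
            raise TableFormatError(f"{path}: subject {s} phase {ph} lacks the t=0 fasting draw")
    df["time_min"] = df["time_min"].astype(int)
    return df


def write_subjects(subjects: pd.DataFrame, path: str, provenance: dict | None = None) -> None:
    _write_tsv(subjects, path, provenance)


def read_fingerprints(path: str, delimiter: str | None = None) -> list[Fingerprint]:
    """Read (id, bitstring-or-hex) rows; hex expands MSB-first, 4 bits/digit."""
    delim = _delimiter(path, delimiter)
    fps: list[Fingerprint] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split(delim)
            if lineno == 1 and parts[0].lower() in ("metabolite_id", "id"):
                continue
            if len(parts) != 2:
                raise TableFormatError(f"{path}:{lineno}: expected 2 fields, got {len(parts)}")
            mid, code = parts[0].strip(), parts[1].strip()
            if set(code) <= {"0", "1"} and code:
                bits = np.frombuffer(code.encode(), dtype=np.uint8) == ord("1")
            else:
                try:
                    value = int(code, 16)
                except ValueError:
                    raise TableFormatError(
                        f"{path}:{lineno}: fingerprint is neither a bitstring nor hex") from None
                n = 4 * len(code)
                bits = np.array([(value >> (n - 1 - i)) & 1 for i in range(n)], dtype=bool)
            fps.append(Fingerprint(metabolite_id=mid, bits=bits))
    lengths = {fp.n_bits for fp in fps}
    if len(lengths) > 1:
        offenders = sorted({fp.metabolite_id for fp in fps
                            if fp.n_bits != fps[0].n_bits})
        raise TableFormatError(
            f"{path}: mixed fingerprint lengths {sorted(lengths)}; offending ids {offenders}")
    return fps


def write_fingerprints(fps: list[Fingerprint], path: str) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("metabolite_id\tbits\n")
        for fp in fps:
            bitstr = "".join("1" if b else "0" for b in fp.bits)
            fh.write(f"{fp.metabolite_id}\t{bitstr}\n")


def direction_of(loading: float, eps: float = 0.0) -> str:
    """Map a signed LV1 loading to the tri-state direction attribute."""
    if loading is None or (isinstance(loading, float) and np.isnan(loading)):
        return "unclear"
    if loading > eps:
        return "increase"
    if loading < -eps:
        return "decrease"
    return "unclear"


def write_network_graphml(network: nx.Graph, path: str) -> None:
    """Write a chemical-similarity network with typed attributes.

    Vertices carry loading_lv1 (signed), size (= |loading_lv1|) and
    direction in {increase, decrease, unclear}; edges carry tanimoto.
    The document round-trips through :func:`read_network_graphml`.
    """
    g = nx.Graph()
    for node, data in network.nodes(data=True):
        loading = float(data.get("loading_lv1", float("nan")))
        g.add_node(str(node),
                   loading_lv1=loading,
                   size=abs(loading) if np.isfinite(loading) else 0.0,
                   direction=data.get("direction", direction_of(loading)))
    for a, b, data in network.edges(data=True):
        g.add_edge(str(a), str(b), tanimoto=float(data["tanimoto"]))
    nx.write_graphml(g, path)


def read_network_graphml(path: str) -> nx.Graph:
    return nx.read_graphml(path)


def _write_tsv(df: pd.DataFrame, path: str, provenance: dict | None = None) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        if provenance:
            for k, v in provenance.items():
                fh.write(f"# {k}: {v}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.10g")


def write_json(obj, path: str) -> None:
    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serializable: {type(o)}")
    os.makedirs(os.path.dirname(os.path.abspath(path)), exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(obj, fh, indent=2, default=_default)
        fh.write("\n")
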