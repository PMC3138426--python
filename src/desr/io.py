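"""Readers, writers and packaged fixtures for trial tables and designs.

Trial-count tables are UTF-8 comma-delimited text with a mandatory header
``trial_id,n1,r1,p1,n_tot,r_tot,p_tot,investigator_stopped``; counts are
integers with explicit denominators (the source tables print "13/30"-style
cells whose denominators vary per trial), stage-II counts are cumulative,
and blank means missing (the three cumulative fields blank together).

The package bundles, as fixtures, the published DESR threshold tables (one
for the Fleming-sized design, two accrual-matched tables for the Gehan
cohort) and the two historical cohorts with their printed verdict cells.
Fixture files carry SHA-256 checksums; loaders fail loudly on drift.
"""

from __future__ import annotations

import hashlib
import json
from importlib import resources
from pathlib import Path
from typing import Sequence, Union

import pandas as pd

from .design import DesrThresholds, DualHypotheses, TrialRecord, ValidationError
from .search import SearchConstraints

__all__ = [
    "read_trial_table",
    "write_trial_table",
    "read_threshold_table",
    "write_threshold_table",
    "load_cohort",
    "load_threshold_fixture",
    "load_decision_cells",
    "read_design_spec",
    "FIXTURE_SHA256",
]

_TRIAL_COLUMNS = ["trial_id", "n1", "r1", "p1", "n_tot", "r_tot", "p_tot", "investigator_stopped"]

#: checksums of the packaged fixtures (verified on every load)
FIXTURE_SHA256 = {
    "fleming_sized_thresholds.csv": "8dbc0c5af24ca9398e40204f23f2eefe2efae2f722072f4f532c29b87713646a",
    "gehan_matched_thresholds_epd46.csv": "c2a31af373e271f890e82fb067c75171df9815b1c2741b832d1eb3a312d9bc8a",
    "gehan_matched_thresholds_epd35.csv": "6707f4df3a8e6371c50b0ecc68c33835d6308da4f6041eb885c33fc80ca52e3f",
    "fleming_cohort.csv": "132fbc9a5bde8df1b6baefd3d184dd7321643ff0907033ec78cc9e5a3ff57234",
    "gehan_cohort.csv": "96c2d24eb2768b336ffe97f00b9ef8581ca2be77677ee4b117c94bc2876ea563",
    "fleming_cohort_decisions.csv": "0d11524001153bc1ecc892e3f1b5afd2a09cce8e1298cce7153171341fee319d",
    "gehan_cohort_decisions.csv": "e014895e975036839384db4eb63bea5f4f6e1e0832c852ded06060dc18607bb1",
}


def _fixture_path(name: str) -> Path:
    return Path(resources.files("desr").joinpath("data", name))


def _verify_fixture(name: str) -> Path:
    path = _fixture_path(name)
    digest = hashlib.sha256(path.read_bytes()).hexdigest()
    expected = FIXTURE_SHA256[name]
    if digest != expected:
        raise ValidationError(
            f"fixture {name} failed its integrity check "
            f"(sha256 {digest}, expected {expected})"
        )
    return path


def read_trial_table(path: Union[str, Path]) -> list[TrialRecord]:
    """Read a delimited trial-count table into validated records.

    Malformed rows raise with the offending line number; invariant breaches
    raise naming the trial id.
    """
    df = pd.read_csv(path, dtype={"trial_id": str})
    missing = [c for c in _TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"trial table {path} is missing columns: {missing}")
    records = []
    for line, row in enumerate(df.itertuples(index=False), start=2):
        cum = [row.n_tot, row.r_tot, row.p_tot]
        present = [pd.notna(v) for v in cum]
        if any(present) and not all(present):
            raise ValidationError(
                f"{path} line {line}: n_tot/r_tot/p_tot must be blank together or present together"
            )
        try:
            records.append(
                TrialRecord(
                    trial_id=str(row.trial_id),
                    n1=int(row.n1),
                    r1=int(row.r1),
                    p1=int(row.p1),
                    n_tot=int(row.n_tot) if present[0] else None,
                    r_tot=int(row.r_tot) if present[0] else None,
                    p_tot=int(row.p_tot) if present[0] else None,
                    investigator_stopped=_parse_bool(row.investigator_stopped),
                )
            )
        except (TypeError, ValueError) as exc:
            raise ValidationError(f"{path} line {line}: {exc}") from exc
    return records


def _parse_bool(v) -> bool:
    if isinstance(v, bool):
        return v
    if pd.isna(v):
        return False
    s = str(v).strip().lower()
    if s in {"true", "1", "yes"}:
        return True
    if s in {"false", "0", "no", ""}:
        return False
    raise ValidationError(f"investigator_stopped must be boolean, got {v!r}")


def write_trial_table(records: Sequence[TrialRecord], path: Union[str, Path]) -> None:
    """Write records in the canonical column order (round-trips exactly)."""
    rows = []
    for r in records:
        rows.append(
            {
                "trial_id": r.trial_id,
                "n1": r.n1,
                "r1": r.r1,
                "p1": r.p1,
                "n_tot": r.n_tot,
                "r_tot": r.r_tot,
                "p_tot": r.p_tot,
                "investigator_stopped": "true" if r.investigator_stopped else "false",
            }
        )
    df = pd.DataFrame(rows, columns=_TRIAL_COLUMNS)
    df.to_csv(path, index=False)


_THRESHOLD_COLUMNS = [
    "r_alt", "r_nul", "epd_alt", "epd_nul",
    "n1", "n2", "s_r", "s_p", "a_r", "a_p",
    "power", "alpha", "en_nul", "pes_nul", "en_alt", "pes_alt",
]


def read_threshold_table(path: Union[str, Path]) -> pd.DataFrame:
    """Read a threshold-derivation table (bounds plus OC columns)."""
    df = pd.read_csv(path)
    missing = [c for c in _THRESHOLD_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"threshold table {path} is missing columns: {missing}")
    return df


def write_threshold_table(df: pd.DataFrame, path: Union[str, Path]) -> None:
    df.to_csv(path, index=False, columns=[c for c in _THRESHOLD_COLUMNS if c in df.columns])


def thresholds_from_row(row) -> DesrThresholds:
    """Build a validated threshold set from one table row."""
    return DesrThresholds(
        n1=int(row["n1"]), n2=int(row["n2"]),
        s_r=int(row["s_r"]), s_p=int(row["s_p"]),
        a_r=int(row["a_r"]), a_p=int(row["a_p"]),
    )


def load_threshold_fixture(name: str) -> list[tuple[int, DesrThresholds]]:
    """Load a bundled threshold table as ``(n2, thresholds)`` rows.

    ``name`` is one of ``fleming_epd46``, ``fleming_epd35`` (the two rows of
    the Fleming-sized table) or ``gehan_epd46``, ``gehan_epd35`` (the
    accrual-matched tables).
    """
    files = {
        "fleming_epd46": ("fleming_sized_thresholds.csv", 0.4),
        "fleming_epd35": ("fleming_sized_thresholds.csv", 0.3),
        "gehan_epd46": ("gehan_matched_thresholds_epd46.csv", None),
        "gehan_epd35": ("gehan_matched_thresholds_epd35.csv", None),
    }
    if name not in files:
        raise LookupError(f"unknown threshold fixture: {name!r} (have {sorted(files)})")
    fname, epd_alt = files[name]
    df = read_threshold_table(_verify_fixture(fname))
    if epd_alt is not None:
        df = df[df["epd_alt"] == epd_alt]
    return [(int(row["n2"]), thresholds_from_row(row)) for _, row in df.iterrows()]


def load_cohort(name: str) -> list[TrialRecord]:
    """Load a bundled historical cohort (``fleming_cohort`` or
    ``gehan_cohort``)."""
    if name not in {"fleming_cohort", "gehan_cohort"}:
        raise LookupError(f"unknown cohort: {name!r}")
    return read_trial_table(_verify_fixture(f"{name}.csv"))


def load_decision_cells(name: str) -> pd.DataFrame:
    """Load the printed verdict cells for a bundled cohort.

    Stage-1 columns hold Y/N; activity columns hold Y (null rejected),
    N (null accepted) or P/? (no stage-II data, verdict indeterminate).
    """
    if name not in {"fleming_cohort", "gehan_cohort"}:
        raise LookupError(f"unknown cohort: {name!r}")
    return pd.read_csv(_verify_fixture(f"{name}_decisions.csv"), dtype=str)


_SPEC_KEYS = {
    "hypotheses": {"r_nul", "r_alt", "epd_nul", "epd_alt"},
    "stages": {"n1", "n2", "n2_list"},
    "constraints": {"alpha_max", "power_min", "selection"},
    "thresholds": {"n1", "n2", "s_r", "s_p", "a_r", "a_p"},
}


def read_design_spec(path: Union[str, Path]) -> dict:
    """Read and validate a JSON design specification.

    Top-level sections: ``hypotheses`` (required), ``stages``,
    ``constraints``, ``thresholds`` (optional explicit bounds).  Unknown
    keys at any level are rejected; values are validated by the domain
    types they construct.
    """
    with open(path, encoding="utf-8") as fh:
        raw = json.load(fh)
    unknown = set(raw) - set(_SPEC_KEYS)
    if unknown:
        raise ValidationError(f"design spec {path}: unknown sections {sorted(unknown)}")
    if "hypotheses" not in raw:
        raise ValidationError(f"design spec {path}: missing 'hypotheses' section")
    for section, allowed in _SPEC_KEYS.items():
        if section in raw:
            bad = set(raw[section]) - allowed
            if bad:
                raise ValidationError(
                    f"design spec {path}: unknown keys in '{section}': {sorted(bad)}"
                )
    out: dict = {"hypotheses": DualHypotheses(**raw["hypotheses"])}
    if "stages" in raw:
        out["stages"] = dict(raw["stages"])
    if "constraints" in raw:
        c = dict(raw["constraints"])
        if "selection" in c:
            c["selection"] = tuple(c["selection"])
        out["constraints"] = SearchConstraints(**c)
    if "thresholds" in raw:
        out["thresholds"] = DesrThresholds(**raw["thresholds"])
    return out
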