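"""Head-to-head application of stopping-rule sets to a trial cohort.

A rule set is any callable mapping a :class:`~desr.design.TrialRecord` to a
:class:`~desr.design.Decision`; constructors below wrap the DESR, Fleming
and Gehan rules, including the accrual-matched variant of the DESR that
picks the threshold row whose planned stage-II size matches each trial's
realised accrual.

The report carries every per-trial decision plus summary tallies (stage-I
stops, rejections, pairwise cross-stops and agreements); the summaries are
always recomputable from the per-trial rows, and a dedicated tally excludes
trials halted by their investigators from "continuing" counts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

from .classic import FlemingThresholds, GehanDesign, decide_fleming, decide_gehan
from .design import Decision, DesrThresholds, TrialRecord, Verdict, _check, decide_desr

__all__ = [
    "RuleSet",
    "ComparisonReport",
    "desr_rule",
    "desr_table_rule",
    "fleming_rule",
    "gehan_rule",
    "select_thresholds_for_record",
    "compare_cohort",
]

RuleSet = Callable[[TrialRecord], Decision]


def desr_rule(th: DesrThresholds) -> RuleSet:
    """One fixed DESR threshold set applied to every record."""
    return lambda record: decide_desr(record, th)


def desr_table_rule(table: Sequence[tuple[int, DesrThresholds]]) -> RuleSet:
    """Accrual-matched DESR: thresholds are looked up per record by its
    realised stage-II size (see :func:`select_thresholds_for_record`)."""
    return lambda record: decide_desr(record, select_thresholds_for_record(table, record))


def fleming_rule(th: FlemingThresholds) -> RuleSet:
    return lambda record: decide_fleming(record, th)


def gehan_rule(design: GehanDesign | None = None) -> RuleSet:
    design = design if design is not None else GehanDesign()
    return lambda record: decide_gehan(record, design)


def select_thresholds_for_record(
    table: Sequence[tuple[int, DesrThresholds]], record: TrialRecord
) -> DesrThresholds:
    """Pick the threshold row whose planned n2 equals the record's realised
    stage-II accrual (``n_tot - n1``).

    A record with no cumulative data falls back to the table's first row,
    legal only because derivation tables hold stage-I bounds constant across
    rows (asserted here); such a record's verdict can only depend on the
    stage-I bounds.

    Raises
    ------
    LookupError
        Naming the stage-II size sought, when no row matches.
    """
    _check(len(table) > 0, "threshold table must be nonempty")
    if not record.has_stage2:
        s1 = {(th.s_r, th.s_p) for _, th in table}
        if len(s1) != 1:
            raise LookupError(
                f"trial {record.trial_id} has no cumulative data and the table's "
                "stage-I bounds differ across rows; cannot select thresholds"
            )
        return table[0][1]
    n2 = record.n_tot - record.n1
    for planned_n2, th in table:
        if planned_n2 == n2:
            return th
    raise LookupError(f"no threshold row with n2 = {n2} (trial {record.trial_id})")


@dataclass(frozen=True)
class ComparisonReport:
    """Per-trial decisions of several rule sets plus summary tallies.

    ``summaries`` keys:

    - ``stage1_stops[rule]``, ``rejections[rule]``, ``acceptances[rule]``,
      ``indeterminate[rule]`` — per-rule verdict tallies;
    - ``continuing_not_investigator_stopped[rule]`` — trials the rule let
      continue that were not halted by their investigators;
    - ``stopped_by_A_continued_by_B[(A, B)]`` — cross-rule stage-I tallies;
    - ``final_agreement[(A, B)]`` — trials whose final verdicts coincide
      (two indeterminate verdicts agree; a determinate vs an indeterminate
      verdict does not).
    """

    rule_names: tuple[str, ...]
    per_trial: tuple[tuple[str, dict[str, Decision]], ...]
    summaries: dict


def _summarise(
    records: Sequence[TrialRecord],
    rule_names: Sequence[str],
    decisions: Sequence[Mapping[str, Decision]],
) -> dict:
    stops = {name: 0 for name in rule_names}
    rejs = {name: 0 for name in rule_names}
    accs = {name: 0 for name in rule_names}
    indet = {name: 0 for name in rule_names}
    cont_ok = {name: 0 for name in rule_names}
    cross = {(a, b): 0 for a in rule_names for b in rule_names if a != b}
    agree = {(a, b): 0 for a in rule_names for b in rule_names if a < b}

    for rec, dec in zip(records, decisions):
        for name in rule_names:
            d = dec[name]
            stops[name] += d.stage1_stop
            rejs[name] += d.final is Verdict.REJECT_NULL
            accs[name] += d.final is Verdict.ACCEPT_NULL
            indet[name] += d.final is Verdict.INDETERMINATE
            cont_ok[name] += (not d.stage1_stop) and (not rec.investigator_stopped)
        for a in rule_names:
            for b in rule_names:
                if a != b and dec[a].stage1_stop and not dec[b].stage1_stop:
                    cross[(a, b)] += 1
        for a, b in agree:
            agree[(a, b)] += dec[a].final is dec[b].final

    return {
        "stage1_stops": stops,
        "rejections": rejs,
        "acceptances": accs,
        "indeterminate": indet,
        "continuing_not_investigator_stopped": cont_ok,
        "stopped_by_A_continued_by_B": cross,
        "final_agreement": agree,
    }


def compare_cohort(
    records: Sequence[TrialRecord], rule_sets: Mapping[str, RuleSet]
) -> ComparisonReport:
    """Apply every rule set to every record and tally the results.

    Raises
    ------
    ValidationError / LookupError
        Propagated from the rule sets, with the trial id attached.
    """
    _check(len(records) > 0, "cohort must be nonempty")
    _check(len(rule_sets) > 0, "rule_sets must be nonempty")
    names = tuple(rule_sets)
    per_trial = []
    decisions = []
    for rec in records:
        row: dict[str, Decision] = {}
        for name, rule in rule_sets.items():
            try:
                row[name] = rule(rec)
            except (ValueError, LookupError) as exc:
                raise type(exc)(f"rule '{name}' failed on trial {rec.trial_id}: {exc}") from exc
        per_trial.append((rec.trial_id, row))
        decisions.append(row)
    summaries = _summarise(records, names, decisions)
    return ComparisonReport(
        rule_names=names, per_trial=tuple(per_trial), summaries=summaries
    )
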