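"""Ct-based qPCR quantitation: ChIP percent enrichment, DRIP fold, 2^-ddCt.

All formulas work on cycle-threshold (Ct) values with a base-2
amplification model: one cycle difference corresponds to a twofold
difference in starting template.  Dilution factors enter as
``log2(dilution)`` corrections, matching how a diluted input well shifts
its Ct.

Three quantitation modes:

* **ChIP percent enrichment** — percent of input recovered by the IP,
  optionally mock-subtracted:
  ``100 * 2^(Ct_input - Ct_IP - log2(d)) - 100 * 2^(Ct_input - Ct_mock - log2(d))``.
* **DRIP fold enrichment** — ``2^(Ct_input - log2(d) - Ct_DRIP)``, with an
  optional empty-bead mock IP subtracted on the fold scale.
* **comparative Ct (2^-ddCt)** — fold change of a target against a
  reference locus, treated versus control sample.

Replicate Cts within a (sample, locus, role) group are averaged on the Ct
scale before formula evaluation by default; the spread of derived values is
reported from replicate-wise evaluation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from statistics import mean, stdev
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "CtRecord",
    "QuantResult",
    "ROLES",
    "chip_percent_enrichment",
    "drip_fold_enrichment",
    "mock_corrected_drip",
    "ddct_fold",
    "relative_normalize",
    "select_linear_dilution",
    "read_ct_table",
    "write_ct_table",
    "write_quant_table",
    "quantify_chip",
    "quantify_drip",
    "quantify_ddct",
]

ROLES = ("input", "ip", "mock", "drip", "reference")

BELOW_BACKGROUND = "below_background"
OUT_OF_RANGE = "ct_out_of_linear_range"

#: Default Ct window treated as the linear amplification range.
DEFAULT_CT_WINDOW = (15.0, 32.0)


@dataclass(frozen=True)
class CtRecord:
    """One qPCR well: sample, primer-set locus, role, dilution and Ct."""

    sample: str
    locus: str
    role: str
    dilution: float
    ct: float
    replicate: int = 1

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValueError(f"unknown role {self.role!r}; expected one of {ROLES}")
        if not (self.dilution > 0):
            raise ValueError(f"dilution must be > 0, got {self.dilution}")
        if not math.isfinite(self.ct):
            raise ValueError(f"Ct must be finite, got {self.ct}")


@dataclass(frozen=True)
class QuantResult:
    """One derived quantity for a (sample, locus) pair."""

    sample: str
    locus: str
    value: float
    kind: str  # percent_enrichment | fold_over_input | ddct_fold | relative_fold
    sd: float = float("nan")
    flags: tuple[str, ...] = ()


def _require_finite(**cts: float) -> None:
    for name, value in cts.items():
        if value is None:
            continue
        if not math.isfinite(value):
            raise ValueError(f"{name} must be finite, got {value}")


def chip_percent_enrichment(
    ct_input: float,
    ct_ip: float,
    ct_mock: float | None = None,
    dilution: float = 1.0,
) -> float:
    """Percent of input DNA recovered by the IP, optionally mock-subtracted.

    ``100 * 2^(Ct_input - Ct_IP - log2(dilution))`` minus, when a mock-IP Ct
    is given, the same expression evaluated with the mock Ct.  A negative
    result means the mock recovered more than the IP (below background).
    """
    _require_finite(ct_input=ct_input, ct_ip=ct_ip, ct_mock=ct_mock)
    if not (dilution > 0):
        raise ValueError(f"dilution must be > 0, got {dilution}")
    log_d = math.log2(dilution)
    value = 100.0 * 2.0 ** (ct_input - ct_ip - log_d)
    if ct_mock is not None:
        value -= 100.0 * 2.0 ** (ct_input - ct_mock - log_d)
    return value


def drip_fold_enrichment(ct_input: float, ct_drip: float, dilution: float = 1.0) -> float:
    """RNA-DNA hybrid fold enrichment over input: ``2^(Ct_input - log2(d) - Ct_DRIP)``."""
    _require_finite(ct_input=ct_input, ct_drip=ct_drip)
    if not (dilution > 0):
        raise ValueError(f"dilution must be > 0, got {dilution}")
    return 2.0 ** (ct_input - math.log2(dilution) - ct_drip)


def mock_corrected_drip(raw: QuantResult, mock: QuantResult) -> QuantResult:
    """Subtract the empty-bead mock-IP enrichment from a DRIP enrichment.

    Values at or below the mock background are reported as-is (possibly
    zero or negative) with a ``below_background`` flag, never clipped.
    """
    if (raw.sample, raw.locus) != (mock.sample, mock.locus):
        raise ValueError(
            f"mock correction mismatch: {raw.sample}/{raw.locus} vs "
            f"{mock.sample}/{mock.locus}"
        )
    value = raw.value - mock.value
    flags = raw.flags
    if value <= 0:
        flags = tuple(dict.fromkeys(flags + (BELOW_BACKGROUND,)))
    return replace(raw, value=value, flags=flags)


def ddct_fold(
    ct_target_treated: float,
    ct_ref_treated: float,
    ct_target_control: float,
    ct_ref_control: float,
) -> float:
    """Comparative-Ct fold change: ``2^-((dCt_treated) - (dCt_control))``

    where ``dCt = Ct_target - Ct_reference`` within each condition.
    """
    _require_finite(
        ct_target_treated=ct_target_treated,
        ct_ref_treated=ct_ref_treated,
        ct_target_control=ct_target_control,
        ct_ref_control=ct_ref_control,
    )
    ddct = (ct_target_treated - ct_ref_treated) - (ct_target_control - ct_ref_control)
    return 2.0 ** (-ddct)


def relative_normalize(
    results: Sequence[QuantResult], reference_sample: str
) -> list[QuantResult]:
    """Divide every value by the reference sample's value at the same locus.

    This is the final normalisation step of the ChIP workflow (each group
    relative to untreated wild type); the reference sample maps to 1.0 and
    all results become ``relative_fold``.
    """
    ref_by_locus: dict[str, float] = {}
    for r in results:
        if r.sample == reference_sample:
            ref_by_locus[r.locus] = r.value
    out: list[QuantResult] = []
    for r in results:
        ref = ref_by_locus.get(r.locus)
        if ref is None:
            raise ValueError(
                f"relative_normalize: no result for reference sample "
                f"{reference_sample!r} at locus {r.locus!r}"
            )
        if not (ref > 0):
            raise ValueError(
                f"relative_normalize: non-positive reference value {ref} at "
                f"locus {r.locus!r}"
            )
        sd = r.sd / ref if math.isfinite(r.sd) else r.sd
        out.append(replace(r, value=r.value / ref, sd=sd, kind="relative_fold"))
    return out


def select_linear_dilution(
    records: Sequence[CtRecord],
    ct_window: tuple[float, float] = DEFAULT_CT_WINDOW,
) -> dict[tuple[str, str, str], tuple[CtRecord, tuple[str, ...]]]:
    """Pick, per (sample, locus, role), the dilution whose Ct sits in the linear range.

    Wells are run at several dilutions; the one whose Ct lies inside
    ``ct_window`` (nearest the window midpoint if several qualify) is kept.
    If no well falls inside the window the nearest one is returned carrying
    an out-of-range flag.
    """
    lo, hi = ct_window
    if not (lo < hi):
        raise ValueError(f"invalid ct_window {ct_window}")
    mid = (lo + hi) / 2.0
    groups: dict[tuple[str, str, str], list[CtRecord]] = {}
    for rec in records:
        groups.setdefault((rec.sample, rec.locus, rec.role), []).append(rec)
    if not groups:
        raise ValueError("select_linear_dilution: no records")
    selected: dict[tuple[str, str, str], tuple[CtRecord, tuple[str, ...]]] = {}
    for key, group in groups.items():
        inside = [r for r in group if lo <= r.ct <= hi]
        if inside:
            best = min(inside, key=lambda r: (abs(r.ct - mid), r.dilution, r.replicate))
            selected[key] = (best, ())
        else:
            def dist(r: CtRecord) -> float:
                return lo - r.ct if r.ct < lo else r.ct - hi

            best = min(group, key=lambda r: (dist(r), r.dilution, r.replicate))
            selected[key] = (best, (OUT_OF_RANGE,))
    return selected


# -- table-level pipelines --------------------------------------------------

_CT_COLS = ["sample", "locus", "role", "dilution", "ct", "replicate"]


def read_ct_table(path: str | Path) -> list[CtRecord]:
    """Read a Ct plate TSV (``sample locus role dilution ct replicate``)."""
    df = pd.read_csv(path, sep="\t", float_precision="round_trip", dtype={"sample": str, "locus": str, "role": str})
    missing = [c for c in _CT_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: Ct table missing columns {missing}")
    return [
        CtRecord(
            sample=row.sample,
            locus=row.locus,
            role=row.role,
            dilution=float(row.dilution),
            ct=float(row.ct),
            replicate=int(row.replicate),
        )
        for row in df.itertuples(index=False)
    ]


def write_ct_table(records: Sequence[CtRecord], path: str | Path) -> None:
    pd.DataFrame(
        {
            "sample": [r.sample for r in records],
            "locus": [r.locus for r in records],
            "role": [r.role for r in records],
            "dilution": [r.dilution for r in records],
            "ct": [r.ct for r in records],
            "replicate": [r.replicate for r in records],
        }
    ).to_csv(path, sep="\t", index=False, float_format="%.17g")


def write_quant_table(results: Sequence[QuantResult], path: str | Path) -> None:
    """Write derived quantities as TSV (``sample locus kind value sd flags``)."""
    pd.DataFrame(
        {
            "sample": [r.sample for r in results],
            "locus": [r.locus for r in results],
            "kind": [r.kind for r in results],
            "value": [r.value for r in results],
            "sd": [r.sd for r in results],
            "flags": [";".join(r.flags) for r in results],
        }
    ).to_csv(path, sep="\t", index=False, float_format="%.17g")


def _group_cts(
    records: Sequence[CtRecord],
) -> dict[tuple[str, str, str], list[CtRecord]]:
    groups: dict[tuple[str, str, str], list[CtRecord]] = {}
    for rec in records:
        groups.setdefault((rec.sample, rec.locus, rec.role), []).append(rec)
    for group in groups.values():
        group.sort(key=lambda r: r.replicate)
        dilutions = {r.dilution for r in group}
        if len(dilutions) > 1:
            raise ValueError(
                "multiple dilution factors within a (sample, locus, role) "
                "group; run select_linear_dilution first"
            )
    return groups


def _mean_ct(group: Sequence[CtRecord]) -> float:
    return mean(r.ct for r in group)


def _replicate_values(groups_cts: Sequence[Sequence[float]], fn) -> list[float]:
    """Evaluate *fn* per matched replicate index (truncated to shortest group)."""
    n = min(len(g) for g in groups_cts)
    return [fn(*(g[i] for g in groups_cts)) for i in range(n)]


def _sd(values: Sequence[float]) -> float:
    return stdev(values) if len(values) > 1 else float("nan")


def quantify_drip(
    records: Sequence[CtRecord],
    subtract_mock: bool = True,
    average: str = "ct",
) -> list[QuantResult]:
    """DRIP fold enrichment over input per (sample, locus), mock-subtracted.

    ``average='ct'`` (default) averages replicate Cts before applying the
    fold formula; ``average='value'`` averages replicate-wise folds instead.
    """
    if average not in ("ct", "value"):
        raise ValueError(f"average must be 'ct' or 'value', got {average!r}")
    groups = _group_cts(records)
    out: list[QuantResult] = []
    pairs = sorted(
        {(s, l) for (s, l, role) in groups if role == "drip"}
    )
    for sample, locus in pairs:
        inp = groups.get((sample, locus, "input"))
        drip = groups.get((sample, locus, "drip"))
        if inp is None or drip is None:
            raise ValueError(f"quantify_drip: missing input/drip wells for {sample}/{locus}")
        dilution = drip[0].dilution

        def fold(ci: float, cd: float) -> float:
            return drip_fold_enrichment(ci, cd, dilution)

        rep_vals = _replicate_values([[r.ct for r in inp], [r.ct for r in drip]], fold)
        value = fold(_mean_ct(inp), _mean_ct(drip)) if average == "ct" else mean(rep_vals)
        result = QuantResult(sample, locus, value, "fold_over_input", sd=_sd(rep_vals))
        mock = groups.get((sample, locus, "mock"))
        if subtract_mock and mock is not None:
            mock_vals = _replicate_values(
                [[r.ct for r in inp], [r.ct for r in mock]],
                lambda ci, cm: drip_fold_enrichment(ci, cm, mock[0].dilution),
            )
            mock_value = (
                drip_fold_enrichment(_mean_ct(inp), _mean_ct(mock), mock[0].dilution)
                if average == "ct"
                else mean(mock_vals)
            )
            mock_result = QuantResult(sample, locus, mock_value, "fold_over_input")
            result = mock_corrected_drip(result, mock_result)
        out.append(result)
    return out


def quantify_chip(
    records: Sequence[CtRecord],
    reference_sample: str | None = None,
    average: str = "ct",
) -> list[QuantResult]:
    """ChIP percent enrichment per (sample, locus), mock-subtracted when present.

    When *reference_sample* is given, percentages are additionally
    normalised per locus to that sample (relative fold of enrichment).
    """
    if average not in ("ct", "value"):
        raise ValueError(f"average must be 'ct' or 'value', got {average!r}")
    groups = _group_cts(records)
    out: list[QuantResult] = []
    pairs = sorted({(s, l) for (s, l, role) in groups if role == "ip"})
    for sample, locus in pairs:
        inp = groups.get((sample, locus, "input"))
        ip = groups.get((sample, locus, "ip"))
        if inp is None or ip is None:
            raise ValueError(f"quantify_chip: missing input/ip wells for {sample}/{locus}")
        mock = groups.get((sample, locus, "mock"))
        dilution = ip[0].dilution
        if mock is not None:
            rep_vals = _replicate_values(
                [[r.ct for r in inp], [r.ct for r in ip], [r.ct for r in mock]],
                lambda ci, cp, cm: chip_percent_enrichment(ci, cp, cm, dilution),
            )
            value = (
                chip_percent_enrichment(_mean_ct(inp), _mean_ct(ip), _mean_ct(mock), dilution)
                if average == "ct"
                else mean(rep_vals)
            )
        else:
            rep_vals = _replicate_values(
                [[r.ct for r in inp], [r.ct for r in ip]],
                lambda ci, cp: chip_percent_enrichment(ci, cp, None, dilution),
            )
            value = (
                chip_percent_enrichment(_mean_ct(inp), _mean_ct(ip), None, dilution)
                if average == "ct"
                else mean(rep_vals)
            )
        flags = (BELOW_BACKGROUND,) if value < 0 else ()
        out.append(
            QuantResult(sample, locus, value, "percent_enrichment", sd=_sd(rep_vals), flags=flags)
        )
    if reference_sample is not None:
        out = relative_normalize(out, reference_sample)
    return out


def quantify_ddct(
    records: Sequence[CtRecord],
    control_sample: str,
    average: str = "ct",
) -> list[QuantResult]:
    """2^-ddCt fold change per (sample, target locus) against a control sample.

    Target wells carry role ``ip`` (or ``drip``); the reference locus wells
    carry role ``reference``.  The control sample's own fold is 1 by
    construction and is included for completeness.
    """
    if average not in ("ct", "value"):
        raise ValueError(f"average must be 'ct' or 'value', got {average!r}")
    groups = _group_cts(records)
    target_roles = {role for (_, _, role) in groups if role in ("ip", "drip")}
    if not target_roles:
        raise ValueError("quantify_ddct: no target wells (role 'ip' or 'drip')")
    ref_locus_by_sample: dict[str, tuple[str, str, str]] = {}
    for (sample, locus, role) in groups:
        if role == "reference":
            ref_locus_by_sample[sample] = (sample, locus, role)
    out: list[QuantResult] = []
    pairs = sorted({(s, l) for (s, l, role) in groups if role in target_roles})
    for sample, locus in pairs:
        key_t = next(
            (sample, locus, role) for role in target_roles if (sample, locus, role) in groups
        )
        ref_key = ref_locus_by_sample.get(sample)
        ctrl_t_key = next(
            ((control_sample, locus, role) for role in target_roles
             if (control_sample, locus, role) in groups),
            None,
        )
        ctrl_ref_key = ref_locus_by_sample.get(control_sample)
        if ref_key is None or ctrl_t_key is None or ctrl_ref_key is None:
            raise ValueError(
                f"quantify_ddct: incomplete design for {sample}/{locus} "
                f"(need reference wells and control-sample wells)"
            )
        cts = [
            [r.ct for r in groups[key_t]],
            [r.ct for r in groups[ref_key]],
            [r.ct for r in groups[ctrl_t_key]],
            [r.ct for r in groups[ctrl_ref_key]],
        ]
        rep_vals = _replicate_values(cts, ddct_fold)
        value = (
            ddct_fold(*(mean(g) for g in cts)) if average == "ct" else mean(rep_vals)
        )
        out.append(QuantResult(sample, locus, value, "ddct_fold", sd=_sd(rep_vals)))
    return out
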