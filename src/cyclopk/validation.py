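"""Predicted-vs-experimental validation of the calibration pipeline.

Reproduces the reference analysis chain for each compound:

1. tabulated rate magnitudes from the half-lives (x10^3 display, used at
   face value in min^-1 for the short-range model);
2. precalculated plasma peak (Cmax_pre, Tmax_pre) from the Bateman form;
3. calibration fold = Tmax * Cmax_pre / (Tmax_pre * Cmax) from the
   published rounded peak values;
4. refined rates = raw / fold, and the refined-run peak;
5. validated plasma Cmax by rescaling the refined peak to the
   experimental Tmax: Cmax_validated = Cmax_refined * Tmax_exp / Tmax_refined.

Every chained step consumes the published *rounded* values (the folds
7.14/4.88/5.38 and validated concentrations 39.09/18.46 ng/mL are
reproducible only that way); the full-precision computed values are
reported alongside, and any mismatch beyond one unit in the last printed
digit lands in ``discrepancy_notes`` instead of being silently accepted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

import pandas as pd

from .parameters import (
    CompoundParameters,
    fold_factor,
    hydrophobic_initial_scaling,
    round_half_away,
)
from .shortrange import (
    AdjustmentStrategy,
    apply_hydrophobic_adjustment,
    peak,
    three_compartment_system,
)

__all__ = [
    "PRINTED_TABLE1",
    "PRINTED_TABLE2",
    "TableEntry",
    "ValidationRow",
    "scale_to_experimental",
    "rate_table_report",
    "build_validation_table",
    "validation_frame",
    "HYDROPHOBIC_COMPOUND",
    "HYDROPHOBIC_PLASMA_FACTOR",
]

# Published rate-constant tables (x10^3 display scale), kept as strings so
# each entry's printed precision is known. Raw table first, fold-refined second.
PRINTED_TABLE1: dict[str, tuple[str, str]] = {
    "NC": ("23.1", "7.2"),
    "NC/HPbCD": ("2.88", "2.1"),
    "NC/TAbCD": ("5.28", "1.56"),
}
PRINTED_TABLE2: dict[str, tuple[str, str]] = {
    "NC": ("3.18", "0.99"),
    "NC/HPbCD": ("0.59", "0.43"),
    "NC/TAbCD": ("1.0", "0.29"),
}

#: compound whose short-range run carries the hydrophobic adjustments
HYDROPHOBIC_COMPOUND = "NC/TAbCD"
#: plasma adjustment factor for the hydrophobic complex
HYDROPHOBIC_PLASMA_FACTOR = 2.5


def _decimals(printed: str) -> int:
    return len(printed.split(".")[1]) if "." in printed else 0


@dataclass(frozen=True)
class TableEntry:
    """One computed-vs-printed rate-constant comparison (display scale)."""

    compound: str
    compartment: str
    computed: float  # rounded to the printed precision
    printed: float
    decimals: int
    flagged: bool  # |computed - printed| beyond one unit in the last digit

    @property
    def ulp_distance(self) -> float:
        return abs(self.computed - self.printed) * 10**self.decimals


def rate_table_report(
    compounds: Iterable[CompoundParameters], refined: bool = False
) -> list[TableEntry]:
    """Compare ln2/t_half displays (or refined rates) with the printed table.

    For the raw table the computed value is ln2/t_half on the x10^3 display
    scale rounded to each entry's printed precision. For the refined table
    it is printed-raw / printed-fold (the published chain operates on
    rounded values). Entries more than one unit in the last printed digit
    away are flagged.
    """
    printed_table = PRINTED_TABLE2 if refined else PRINTED_TABLE1
    entries: list[TableEntry] = []
    for compound in compounds:
        if compound.name not in printed_table:
            continue
        printed_pair = printed_table[compound.name]
        if refined:
            fold = _printed_fold(compound)
            raw = [float(v) for v in PRINTED_TABLE1[compound.name]]
            computed_pair = [raw[0] / fold, raw[1] / fold]
        else:
            rates = compound.rate_constants()
            computed_pair = [rates.k_gi * 1e3, rates.k_plasma * 1e3]
        for compartment, printed_str, computed in zip(
            ("gi", "plasma"), printed_pair, computed_pair
        ):
            nd = _decimals(printed_str)
            rounded = round_half_away(computed, nd)
            printed = float(printed_str)
            flagged = abs(rounded - printed) > 10.0 ** (-nd) * (1 + 1e-9)
            entries.append(
                TableEntry(
                    compound=compound.name,
                    compartment=compartment,
                    computed=rounded,
                    printed=printed,
                    decimals=nd,
                    flagged=flagged,
                )
            )
    return entries


def scale_to_experimental(
    cmax_short: float, tmax_short: float, tmax_exp: float
) -> float:
    """Rescale a short-range peak to the experimental time-to-peak.

    The short-range model uses the x10^3 rate magnitudes, which compresses
    time by the same factor; mapping the peak back to plasma units at the
    observed Tmax is Cmax_short * Tmax_exp / Tmax_short. Applied to the
    published rounded refined peaks this reproduces the validated
    concentrations (39.09 and 18.46 ng/mL to two decimals).
    """
    if not (cmax_short > 0 and tmax_short > 0 and tmax_exp > 0):
        raise ValueError("all arguments must be strictly positive")
    return cmax_short * tmax_exp / tmax_short


@dataclass(frozen=True)
class ValidationRow:
    """Predicted-vs-experimental summary for one compound."""

    compound: str
    tmax_pre: float
    cmax_pre: float
    fold: float
    tmax_refined: float
    cmax_refined: float
    cmax_validated: float
    cmax_exp: float
    cmax_exp_sd: float
    within_exp_sd: bool
    strategy: str
    incomplete: bool = False
    discrepancy_notes: tuple[str, ...] = field(default_factory=tuple)


def _printed_fold(compound: CompoundParameters) -> float:
    rep = compound.reported
    return round_half_away(
        fold_factor(compound.tmax_exp, rep.cmax_pre, rep.tmax_pre, compound.cmax_exp),
        2,
    )


def _shortrange_peak(
    name: str,
    k_gi: float,
    k_plasma: float,
    strategy: AdjustmentStrategy | str,
    gi_ratio: Optional[float],
) -> tuple[float, float]:
    """Analytic plasma peak, with hydrophobic adjustments where they apply."""
    if name != HYDROPHOBIC_COMPOUND or gi_ratio is None:
        est = peak(k_gi, k_plasma, 1.0)
        return est.tmax, est.cmax
    adjusted = apply_hydrophobic_adjustment(
        three_compartment_system(k_gi, k_plasma, 1.0),
        ratio=gi_ratio,
        plasma_factor=HYDROPHOBIC_PLASMA_FACTOR,
        strategy=strategy,
    )
    a = adjusted.system.rate_matrix
    est = peak(-a[0, 0], -a[1, 1], adjusted.system.initial_concentrations[0])
    return est.tmax, est.cmax * adjusted.plasma_output_factor


def build_validation_table(
    compounds: Iterable[CompoundParameters],
    strategy: AdjustmentStrategy | str = AdjustmentStrategy.OUTPUT_SCALE,
) -> list[ValidationRow]:
    """One :class:`ValidationRow` per compound, discrepancies surfaced.

    Computed peaks use the printed raw rate magnitudes; the fold, refined
    rates and validated Cmax chain on the published rounded values. Any
    published number our computation does not match at its printed
    precision is listed in ``discrepancy_notes`` with both values.
    Compounds missing experimental fields yield an incomplete row.
    """
    compounds = list(compounds)
    by_name = {c.name: c for c in compounds}
    gi_ratio: Optional[float] = None
    if "NC" in by_name and HYDROPHOBIC_COMPOUND in by_name:
        k_nc = float(PRINTED_TABLE1["NC"][0])
        k_ta = float(PRINTED_TABLE1[HYDROPHOBIC_COMPOUND][0])
        gi_ratio = round_half_away(hydrophobic_initial_scaling(k_nc, k_ta), 2)

    rows: list[ValidationRow] = []
    for compound in compounds:
        notes: list[str] = []
        rep = compound.reported
        if compound.name in PRINTED_TABLE1:
            k_gi_raw, k_plasma_raw = (float(v) for v in PRINTED_TABLE1[compound.name])
        else:
            rates = compound.rate_constants()
            k_gi_raw, k_plasma_raw = rates.k_gi * 1e3, rates.k_plasma * 1e3

        tmax_pre, cmax_pre = _shortrange_peak(
            compound.name, k_gi_raw, k_plasma_raw, strategy, gi_ratio
        )
        _note_mismatch(notes, "Cmax_pre", cmax_pre, rep.cmax_pre, 2)
        _note_mismatch(notes, "Tmax_pre", tmax_pre, rep.tmax_pre, 2)

        incomplete = any(
            v is None for v in (rep.cmax_pre, rep.tmax_pre, rep.cmax_refined, rep.tmax_refined)
        )
        if incomplete:
            # fall back to computed peaks for the chain; mark the row
            fold = round_half_away(
                fold_factor(compound.tmax_exp, cmax_pre, tmax_pre, compound.cmax_exp), 2
            )
            cmax_pre_in, tmax_pre_in = cmax_pre, tmax_pre
        else:
            fold = _printed_fold(compound)
            cmax_pre_in, tmax_pre_in = rep.cmax_pre, rep.tmax_pre

        k_gi_ref = round_half_away(k_gi_raw / fold, 2)
        k_plasma_ref = round_half_away(k_plasma_raw / fold, 2)
        if compound.name in PRINTED_TABLE2:
            for compartment, printed_str, computed in zip(
                ("GI", "plasma"), PRINTED_TABLE2[compound.name], (k_gi_ref, k_plasma_ref)
            ):
                nd = _decimals(printed_str)
                if abs(round_half_away(computed, nd) - float(printed_str)) > 10.0 ** (-nd) * (
                    1 + 1e-9
                ):
                    notes.append(
                        f"refined k_{compartment}: formula gives {computed:.2f}, "
                        f"published table prints {printed_str} (provenance unexplained)"
                    )

        tmax_refined, cmax_refined = _shortrange_peak(
            compound.name, k_gi_ref, k_plasma_ref, strategy, gi_ratio
        )
        _note_mismatch(notes, "Cmax_refined", cmax_refined, rep.cmax_refined, 2)
        _note_mismatch(notes, "Tmax_refined", tmax_refined, rep.tmax_refined, 2)

        if incomplete:
            cmax_ref_in, tmax_ref_in = cmax_refined, tmax_refined
        else:
            cmax_ref_in, tmax_ref_in = rep.cmax_refined, rep.tmax_refined
        cmax_validated = scale_to_experimental(
            cmax_ref_in, tmax_ref_in, compound.tmax_exp
        )
        within = abs(cmax_validated - compound.cmax_exp) <= compound.cmax_exp_sd
        rows.append(
            ValidationRow(
                compound=compound.name,
                tmax_pre=tmax_pre,
                cmax_pre=cmax_pre,
                fold=fold,
                tmax_refined=tmax_refined,
                cmax_refined=cmax_refined,
                cmax_validated=cmax_validated,
                cmax_exp=compound.cmax_exp,
                cmax_exp_sd=compound.cmax_exp_sd,
                within_exp_sd=within,
                strategy=str(
                    strategy.value if isinstance(strategy, AdjustmentStrategy) else strategy
                ),
                incomplete=incomplete,
                discrepancy_notes=tuple(notes),
            )
        )
    return rows


def _note_mismatch(
    notes: list[str], label: str, computed: float, reported: Optional[float], nd: int
) -> None:
    if reported is None:
        return
    if abs(round_half_away(computed, nd) - reported) > 10.0 ** (-nd) * (1 + 1e-9):
        notes.append(
            f"{label}: computed {computed:.{nd}f} vs reported {reported:g}"
        )


def validation_frame(rows: Iterable[ValidationRow]) -> pd.DataFrame:
    """Tabular (CSV-ready) view of validation rows; notes joined by ' | '."""
    records = []
    for r in rows:
        d = {
            "compound": r.compound,
            "tmax_pre_min": r.tmax_pre,
            "cmax_pre_ng_per_ml": r.cmax_pre,
            "fold": r.fold,
            "tmax_refined_min": r.tmax_refined,
            "cmax_refined_ng_per_ml": r.cmax_refined,
            "cmax_validated_ng_per_ml": r.cmax_validated,
            "cmax_exp_ng_per_ml": r.cmax_exp,
            "cmax_exp_sd_ng_per_ml": r.cmax_exp_sd,
            "within_exp_sd": r.within_exp_sd,
            "strategy": r.strategy,
            "incomplete": r.incomplete,
            "discrepancy_notes": " | ".join(r.discrepancy_notes),
        }
        records.append(d)
    return pd.DataFrame.from_records(records)
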