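"""qPCR quantification: ΔΔCt fold changes and efficiency-corrected ChIP levels.

Three closed forms:

* :func:`ddct_fold_change` — the 2^(-ΔΔCt) relative RNA level, with
  ΔCt = mean Ct(target) - mean Ct(reference) per condition and
  ΔΔCt = ΔCt(condition) - ΔCt(control);
* :func:`small_rna_fold_change` — the same arithmetic applied to
  poly(A)-tailed small-RNA RT-qPCR, where the reference species is itself a
  small RNA (e.g. an unaffected germline-cluster piRNA); a named operation so
  reports can label the assay;
* :func:`chip_relative_level` — the efficiency-corrected ChIP ratio

      E_t^Ct_IP(target) * E_r^Ct_input(ref)
      -------------------------------------
      E_r^Ct_IP(ref) * E_t^Ct_input(target)

  with per-amplicon primer efficiencies E in (1, 2].  Note the orientation:
  as written, a *stronger* IP signal at the target (lower Ct_IP) *lowers*
  the value; this is the reciprocal of the Pfaffl-style ratio.  The printed
  orientation is the default; ``pfaffl_orientation=True`` returns the
  reciprocal.

Replicate Ct values are aggregated by arithmetic mean before
exponentiation.  The table interface recomputes each statistic over the
cartesian product of single-replicate choices and reports mean ± SD.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "QpcrMeasurement",
    "ChipSample",
    "ddct_fold_change",
    "small_rna_fold_change",
    "chip_relative_level",
    "read_ct_table",
    "qpcr_table_report",
]


def _check_ct(name: str, values: Sequence[float]) -> tuple[float, ...]:
    vals = tuple(float(v) for v in values)
    if not vals:
        raise ValueError(f"empty Ct replicate set: {name}")
    if any(v <= 0 or not math.isfinite(v) for v in vals):
        raise ValueError(f"Ct values must be positive and finite: {name}")
    return vals


def _check_eff(name: str, e: float) -> float:
    if not 1.0 < e <= 2.0:
        raise ValueError(f"primer efficiency {name} must lie in (1, 2], got {e}")
    return float(e)


@dataclass(frozen=True)
class QpcrMeasurement:
    """Ct replicate sets for (target, reference) x (condition, control)."""

    target: str
    reference: str
    ct_target_condition: tuple[float, ...]
    ct_target_control: tuple[float, ...]
    ct_reference_condition: tuple[float, ...]
    ct_reference_control: tuple[float, ...]
    e_target: float = 2.0
    e_reference: float = 2.0

    def __post_init__(self) -> None:
        for name in (
            "ct_target_condition",
            "ct_target_control",
            "ct_reference_condition",
            "ct_reference_control",
        ):
            object.__setattr__(self, name, _check_ct(name, getattr(self, name)))
        _check_eff("e_target", self.e_target)
        _check_eff("e_reference", self.e_reference)

    def swapped(self) -> "QpcrMeasurement":
        """Target and reference amplicons exchanged."""
        return QpcrMeasurement(
            self.reference,
            self.target,
            self.ct_reference_condition,
            self.ct_reference_control,
            self.ct_target_condition,
            self.ct_target_control,
            self.e_reference,
            self.e_target,
        )


def ddct_fold_change(m: QpcrMeasurement) -> float:
    """Relative RNA level 2^(-ΔΔCt), condition versus control."""
    dct_condition = float(np.mean(m.ct_target_condition)) - float(
        np.mean(m.ct_reference_condition)
    )
    dct_control = float(np.mean(m.ct_target_control)) - float(
        np.mean(m.ct_reference_control)
    )
    return 2.0 ** -(dct_condition - dct_control)


def small_rna_fold_change(m: QpcrMeasurement) -> float:
    """Relative small-RNA level against a small-RNA reference species.

    Same arithmetic as :func:`ddct_fold_change`; named separately so that
    assay reports can distinguish mRNA from small-RNA quantification.
    """
    return ddct_fold_change(m)


@dataclass(frozen=True)
class ChipSample:
    """Per-amplicon Ct for IP and input fractions with primer efficiencies."""

    target: str
    reference: str
    ct_ip_target: float
    ct_input_target: float
    ct_ip_reference: float
    ct_input_reference: float
    e_target: float = 2.0
    e_reference: float = 2.0

    def __post_init__(self) -> None:
        for name in (
            "ct_ip_target",
            "ct_input_target",
            "ct_ip_reference",
            "ct_input_reference",
        ):
            v = float(getattr(self, name))
            if v <= 0 or not math.isfinite(v):
                raise ValueError(f"{name} must be positive and finite")
        _check_eff("e_target", self.e_target)
        _check_eff("e_reference", self.e_reference)

    def swapped(self) -> "ChipSample":
        return ChipSample(
            self.reference,
            self.target,
            self.ct_ip_reference,
            self.ct_input_reference,
            self.ct_ip_target,
            self.ct_input_target,
            self.e_reference,
            self.e_target,
        )


def chip_relative_level(s: ChipSample, pfaffl_orientation: bool = False) -> float:
    """Efficiency-corrected relative DNA level of a ChIP amplicon.

    Default is the orientation given in the module docstring; with
    ``pfaffl_orientation=True`` the reciprocal is returned, which increases
    with IP signal at the target.
    """
    num = s.e_target**s.ct_ip_target * s.e_reference**s.ct_input_reference
    den = s.e_reference**s.ct_ip_reference * s.e_target**s.ct_input_target
    value = num / den
    return 1.0 / value if pfaffl_orientation else value


# ---------------------------------------------------------------------------
# table interface
# ---------------------------------------------------------------------------

CT_COLUMNS = ["assay", "group", "amplicon", "replicate", "ct", "efficiency"]


def read_ct_table(path) -> pd.DataFrame:
    """Read a Ct TSV with columns assay/group/amplicon/replicate/ct/efficiency.

    ``group`` is ``condition``/``control`` for RNA assays and ``ip``/``input``
    for ChIP assays; ``amplicon`` is ``target`` or ``reference``.  A missing
    or empty efficiency column defaults to 2.0.
    """
    df = pd.read_csv(path, sep="\t")
    missing = set(CT_COLUMNS[:5]) - set(df.columns)
    if missing:
        raise ValueError(f"Ct table lacks columns: {sorted(missing)}")
    if "efficiency" not in df.columns:
        df["efficiency"] = 2.0
    df["efficiency"] = df["efficiency"].fillna(2.0)
    return df[CT_COLUMNS + [c for c in df.columns if c not in CT_COLUMNS]]


def _replicate_stats(values: list[float]) -> tuple[float, float]:
    arr = np.asarray(values, float)
    return float(arr.mean()), float(arr.std(ddof=1)) if arr.size > 1 else 0.0


def _assay_kind(groups: set[str]) -> str:
    if groups == {"condition", "control"}:
        return "rna"
    if groups == {"ip", "input"}:
        return "chip"
    raise ValueError(
        f"assay groups must be condition/control or ip/input, got {sorted(groups)}"
    )


def qpcr_table_report(
    df: pd.DataFrame, pfaffl_orientation: bool = False, max_combinations: int = 10_000
) -> pd.DataFrame:
    """Fold change / relative level per assay with replicate-propagated SD.

    For each assay the point estimate uses mean Ct per replicate set; the SD
    is that of the statistic recomputed over every combination of single
    replicates (capped at ``max_combinations``).
    """
    out = []
    for assay, sub in df.groupby("assay", sort=True):
        groups = set(sub["group"])
        kind = _assay_kind(groups)
        cts: dict[tuple[str, str], list[float]] = {}
        effs: dict[str, float] = {}
        for row in sub.itertuples(index=False):
            cts.setdefault((row.amplicon, row.group), []).append(float(row.ct))
            effs[row.amplicon] = float(row.efficiency)
        keys = (
            [("target", "condition"), ("target", "control"),
             ("reference", "condition"), ("reference", "control")]
            if kind == "rna"
            else [("target", "ip"), ("target", "input"),
                  ("reference", "ip"), ("reference", "input")]
        )
        missing = [k for k in keys if k not in cts]
        if missing:
            raise ValueError(f"assay {assay!r} lacks Ct entries for {missing}")

        def statistic(ct_sets: dict[tuple[str, str], Sequence[float]]) -> float:
            if kind == "rna":
                m = QpcrMeasurement(
                    "target",
                    "reference",
                    ct_sets[("target", "condition")],
                    ct_sets[("target", "control")],
                    ct_sets[("reference", "condition")],
                    ct_sets[("reference", "control")],
                    effs.get("target", 2.0),
                    effs.get("reference", 2.0),
                )
                return ddct_fold_change(m)
            s = ChipSample(
                "target",
                "reference",
                float(np.mean(ct_sets[("target", "ip")])),
                float(np.mean(ct_sets[("target", "input")])),
                float(np.mean(ct_sets[("reference", "ip")])),
                float(np.mean(ct_sets[("reference", "input")])),
                effs.get("target", 2.0),
                effs.get("reference", 2.0),
            )
            return chip_relative_level(s, pfaffl_orientation)

        point = statistic(cts)
        combos = list(itertools.islice(
            itertools.product(*[cts[k] for k in keys]), max_combinations
        ))
        values = [
            statistic({k: (v,) for k, v in zip(keys, combo)}) for combo in combos
        ]
        mean, sd = _replicate_stats(values)
        out.append((assay, kind, point, mean, sd, len(values)))
    return pd.DataFrame(
        out,
        columns=["assay", "kind", "estimate", "combination_mean", "combination_sd", "n_combinations"],
    )
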