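"""Histological maturity classification for female albacore ovaries.

An ovary section is summarised by five features: the most advanced group of
oocytes (MAGO), presence of postovulatory follicles (POFs), the extent of
alpha-stage atresia of yolked oocytes, presence of beta-stage atresia, and
presence of maturity markers (residual hydrated oocytes or gamma/delta
atresia, the persistent "brown bodies").  A deterministic rule engine maps
these features to one of eight development classes (C1–C7, with the regressed
state split into C6a/C6b) and from there to a maturity call:

====== ========= ========== ============================================
class  status    activity   development phase
====== ========= ========== ============================================
C1     immature  —          immature (unyolked, no atresia, no markers)
C2     immature  —          developing (early yolked)
C3     mature    active     spawning capable (advanced yolked, no POFs)
C4     mature    active     spawning (migratory nucleus/hydrated and/or POFs)
C5     mature    inactive   regressing (≥50% alpha atresia)
C6a    mature    inactive   regressed 1 (100% alpha atresia)
C6b    mature    inactive   regressed 2 (beta atresia only)
C7     mature    inactive   regenerating (maturity markers only)
====== ========= ========== ============================================

Fish below the macroscopic threshold (70 cm fork length) are classed immature
without histology; above it a development class is required.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Iterable, Optional, Tuple

import pandas as pd

__all__ = [
    "Mago",
    "AlphaAtresia",
    "DevelopmentClass",
    "MaturityStatus",
    "Activity",
    "MaturityCall",
    "OvarySnapshot",
    "InvalidSnapshotError",
    "MACROSCOPIC_IMMATURE_THRESHOLD_CM",
    "classify_ovary",
    "assign_maturity",
    "maturity_for_class",
    "tabulate_classes",
    "read_ovary_table",
    "all_valid_snapshots",
]

#: Fork length (cm) below which fish are classed immature macroscopically,
#: without requiring histology.
MACROSCOPIC_IMMATURE_THRESHOLD_CM = 70.0


class Mago(str, enum.Enum):
    """Most advanced group of oocytes present in the section."""

    UNYOLKED = "unyolked"
    EARLY_YOLKED = "early_yolked"
    ADVANCED_YOLKED = "advanced_yolked"
    MIGRATORY_NUCLEUS = "migratory_nucleus"
    HYDRATED = "hydrated"


#: MAGO levels that contain yolked oocytes at or beyond the advanced stage.
YOLKED_MAGO = frozenset(
    {Mago.ADVANCED_YOLKED, Mago.MIGRATORY_NUCLEUS, Mago.HYDRATED}
)


class AlphaAtresia(str, enum.Enum):
    """Extent of alpha-stage atresia of yolked oocytes (ordinal)."""

    NONE = "none"
    LT50 = "lt50"  # <50% of yolked oocytes atretic
    GE50 = "ge50"  # >=50% atretic, intact advanced oocytes remain
    FULL = "full"  # 100% atretic; no intact advanced oocytes remain


class DevelopmentClass(str, enum.Enum):
    C1 = "C1"
    C2 = "C2"
    C3 = "C3"
    C4 = "C4"
    C5 = "C5"
    C6A = "C6a"
    C6B = "C6b"
    C7 = "C7"


class MaturityStatus(str, enum.Enum):
    MATURE = "mature"
    IMMATURE = "immature"


class Activity(str, enum.Enum):
    ACTIVE = "active"
    INACTIVE = "inactive"
    NOT_APPLICABLE = "not_applicable"


@dataclass(frozen=True)
class MaturityCall:
    status: MaturityStatus
    activity: Activity

    def __post_init__(self) -> None:
        if self.activity is Activity.ACTIVE and self.status is not MaturityStatus.MATURE:
            raise ValueError("activity=active requires status=mature")


class InvalidSnapshotError(ValueError):
    """Raised for feature combinations that cannot occur in a real ovary."""


@dataclass(frozen=True)
class OvarySnapshot:
    """Histological features of one ovary.

    Invariants (validated on construction):

    * ``alpha_atresia=full`` requires an unyolked/early-yolked MAGO — if every
      yolked oocyte is atretic, none remain to be the most advanced group;
    * partial alpha atresia (``lt50``/``ge50``) requires a yolked MAGO — it is
      defined as a fraction of the yolked oocytes present.
    """

    mago: Mago
    pofs_present: bool
    alpha_atresia: AlphaAtresia
    beta_atresia_present: bool
    maturity_markers_present: bool

    def __post_init__(self) -> None:
        if self.alpha_atresia is AlphaAtresia.FULL and self.mago in YOLKED_MAGO:
            raise InvalidSnapshotError(
                "alpha_atresia=full is inconsistent with an intact advanced "
                f"oocyte group (mago={self.mago.value}); a fully atretic clutch "
                "leaves only unyolked/early yolked oocytes"
            )
        if (
            self.alpha_atresia in (AlphaAtresia.LT50, AlphaAtresia.GE50)
            and self.mago not in YOLKED_MAGO
        ):
            raise InvalidSnapshotError(
                "partial alpha atresia (lt50/ge50) requires yolked oocytes to "
                f"be present, but mago={self.mago.value}"
            )


# Rule rows, evaluated most-advanced-evidence first: C4, C3, C5, C6a, C6b,
# C7, C2, C1.  Each predicate sees a validated snapshot.
def _is_c4(s: OvarySnapshot) -> bool:
    # Spawning: migratory nucleus or hydrated and/or POFs; <50% alpha atresia.
    return (
        s.mago in (Mago.MIGRATORY_NUCLEUS, Mago.HYDRATED) or s.pofs_present
    ) and s.alpha_atresia in (AlphaAtresia.NONE, AlphaAtresia.LT50)


def _is_c3(s: OvarySnapshot) -> bool:
    # Spawning capable: advanced yolked, no POFs, <50% alpha atresia.
    return (
        s.mago is Mago.ADVANCED_YOLKED
        and not s.pofs_present
        and s.alpha_atresia in (AlphaAtresia.NONE, AlphaAtresia.LT50)
    )


def _is_c5(s: OvarySnapshot) -> bool:
    # Regressing: yolked oocytes remain but >=50% are alpha-atretic.
    return s.mago in YOLKED_MAGO and s.alpha_atresia is AlphaAtresia.GE50


def _is_c6a(s: OvarySnapshot) -> bool:
    # Regressed 1: the whole clutch alpha-atretic.
    return s.alpha_atresia is AlphaAtresia.FULL


def _is_c6b(s: OvarySnapshot) -> bool:
    # Regressed 2: no alpha atresia but beta atresia present.
    return (
        s.mago in (Mago.UNYOLKED, Mago.EARLY_YOLKED)
        and s.alpha_atresia is AlphaAtresia.NONE
        and s.beta_atresia_present
    )


def _is_c7(s: OvarySnapshot) -> bool:
    # Regenerating: only maturity markers betray prior spawning.
    return (
        s.mago in (Mago.UNYOLKED, Mago.EARLY_YOLKED)
        and s.alpha_atresia is AlphaAtresia.NONE
        and not s.beta_atresia_present
        and s.maturity_markers_present
    )


def _is_c2(s: OvarySnapshot) -> bool:
    return (
        s.mago is Mago.EARLY_YOLKED
        and not s.pofs_present
        and s.alpha_atresia is AlphaAtresia.NONE
        and not s.beta_atresia_present
        and not s.maturity_markers_present
    )


def _is_c1(s: OvarySnapshot) -> bool:
    return (
        s.mago is Mago.UNYOLKED
        and not s.pofs_present
        and s.alpha_atresia is AlphaAtresia.NONE
        and not s.beta_atresia_present
        and not s.maturity_markers_present
    )


_RULES = (
    (DevelopmentClass.C4, _is_c4),
    (DevelopmentClass.C3, _is_c3),
    (DevelopmentClass.C5, _is_c5),
    (DevelopmentClass.C6A, _is_c6a),
    (DevelopmentClass.C6B, _is_c6b),
    (DevelopmentClass.C7, _is_c7),
    (DevelopmentClass.C2, _is_c2),
    (DevelopmentClass.C1, _is_c1),
)

_CLASS_TO_CALL = {
    DevelopmentClass.C1: MaturityCall(MaturityStatus.IMMATURE, Activity.NOT_APPLICABLE),
    DevelopmentClass.C2: MaturityCall(MaturityStatus.IMMATURE, Activity.NOT_APPLICABLE),
    DevelopmentClass.C3: MaturityCall(MaturityStatus.MATURE, Activity.ACTIVE),
    DevelopmentClass.C4: MaturityCall(MaturityStatus.MATURE, Activity.ACTIVE),
    DevelopmentClass.C5: MaturityCall(MaturityStatus.MATURE, Activity.INACTIVE),
    DevelopmentClass.C6A: MaturityCall(MaturityStatus.MATURE, Activity.INACTIVE),
    DevelopmentClass.C6B: MaturityCall(MaturityStatus.MATURE, Activity.INACTIVE),
    DevelopmentClass.C7: MaturityCall(MaturityStatus.MATURE, Activity.INACTIVE),
}


def classify_ovary(snapshot: OvarySnapshot) -> DevelopmentClass:
    """Map an ovary snapshot to its development class.

    Rules are evaluated most-advanced-evidence first (C4, C3, C5, C6a, C6b,
    C7, C2, C1); the first matching row wins.  Every snapshot satisfying the
    :class:`OvarySnapshot` invariants matches exactly one row.
    """
    for dev_class, rule in _RULES:
        if rule(snapshot):
            return dev_class
    raise InvalidSnapshotError(f"no development class matches {snapshot!r}")


def maturity_for_class(dev_class: DevelopmentClass) -> MaturityCall:
    """Maturity status and reproductive activity implied by a class."""
    return _CLASS_TO_CALL[dev_class]


def assign_maturity(
    dev_class: Optional[DevelopmentClass], fork_length_cm: float
) -> MaturityCall:
    """Combine histology with the macroscopic small-fish rule.

    Fish below 70 cm fork length may lack histology and are classed immature
    macroscopically; at or above 70 cm a development class is required.
    """
    if fork_length_cm <= 0:
        raise ValueError(f"fork_length_cm must be positive, got {fork_length_cm}")
    if dev_class is None:
        if fork_length_cm >= MACROSCOPIC_IMMATURE_THRESHOLD_CM:
            raise ValueError(
                f"histology required for fish >= {MACROSCOPIC_IMMATURE_THRESHOLD_CM:g} cm "
                f"(got {fork_length_cm:g} cm with no development class)"
            )
        return MaturityCall(MaturityStatus.IMMATURE, Activity.NOT_APPLICABLE)
    return maturity_for_class(dev_class)


def tabulate_classes(
    records: Iterable[Tuple[DevelopmentClass, MaturityCall]],
) -> pd.DataFrame:
    """Count records by development class, with maturity status and totals.

    Returns a frame with one row per class (C1..C7 always present, zero
    counts included) and a ``total`` row per maturity status.
    """
    counts = {c: 0 for c in DevelopmentClass}
    for dev_class, call in records:
        expected = maturity_for_class(dev_class)
        if call != expected:
            raise ValueError(
                f"maturity call {call} inconsistent with class {dev_class.value}"
            )
        counts[dev_class] += 1
    rows = []
    for dev_class in DevelopmentClass:
        call = maturity_for_class(dev_class)
        rows.append(
            {
                "dev_class": dev_class.value,
                "status": call.status.value,
                "activity": call.activity.value,
                "count": counts[dev_class],
            }
        )
    table = pd.DataFrame(rows)
    return table


def mature_immature_totals(table: pd.DataFrame) -> Tuple[int, int]:
    """Total mature and immature counts from a :func:`tabulate_classes` table."""
    mature = int(table.loc[table["status"] == "mature", "count"].sum())
    immature = int(table.loc[table["status"] == "immature", "count"].sum())
    return mature, immature


_BOOL_TOKENS = {"0": False, "1": True, "true": True, "false": False}


def _parse_bool(value) -> bool:
    if isinstance(value, bool):
        return value
    token = str(value).strip().lower()
    if token not in _BOOL_TOKENS:
        raise ValueError(f"expected 0/1 boolean, got {value!r}")
    return _BOOL_TOKENS[token]


def read_ovary_table(path, sep: str = ",") -> list[OvarySnapshot]:
    """Read a delimited table of ovary snapshots (one row per ovary).

    Columns: ``mago``, ``pofs_present``, ``alpha_atresia``,
    ``beta_atresia_present``, ``maturity_markers_present``; booleans as 0/1,
    enums as lower-case tokens.
    """
    frame = pd.read_csv(path, sep=sep)
    required = [
        "mago",
        "pofs_present",
        "alpha_atresia",
        "beta_atresia_present",
        "maturity_markers_present",
    ]
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise ValueError(f"ovary table missing required columns: {missing}")
    snapshots = []
    for i, row in frame.iterrows():
        try:
            snapshots.append(
                OvarySnapshot(
                    mago=Mago(str(row["mago"]).strip().lower()),
                    pofs_present=_parse_bool(row["pofs_present"]),
                    alpha_atresia=AlphaAtresia(str(row["alpha_atresia"]).strip().lower()),
                    beta_atresia_present=_parse_bool(row["beta_atresia_present"]),
                    maturity_markers_present=_parse_bool(row["maturity_markers_present"]),
                )
            )
        except ValueError as exc:
            raise ValueError(f"row {i}: {exc}") from exc
    return snapshots


def all_valid_snapshots() -> list[OvarySnapshot]:
    """Enumerate the full finite grid of snapshots satisfying the invariants."""
    snapshots = []
    for mago in Mago:
        for pofs in (False, True):
            for alpha in AlphaAtresia:
                for beta in (False, True):
                    for markers in (False, True):
                        try:
                            snapshots.append(
                                OvarySnapshot(mago, pofs, alpha, beta, markers)
                            )
                        except InvalidSnapshotError:
                            continue
    return snapshots
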