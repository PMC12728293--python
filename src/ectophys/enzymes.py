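"""Duplicate QC and activity ratios for muscle enzyme panels.

Four enzymes are assayed in duplicate per animal: citrate synthase (CS, a
mitochondrial-content proxy), cytochrome-c oxidase (COX, aerobic capacity),
electron-transport-system complexes I–III (ETS, maximal mitochondrial flux)
and lactate dehydrogenase (LDH, anaerobic glycolytic capacity).  Duplicates
more than 10% apart are rejected; a rejected enzyme removes only the ratios
that contain it.  Five ratios summarize mitochondrial stoichiometry:
CS:ETS, COX:ETS, CS:LDH, COX:LDH and CS:COX.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = ["ENZYMES", "RATIOS", "EnzymePanel", "duplicate_qc", "compute_ratios"]

ENZYMES = ("CS", "COX", "ETS", "LDH")

#: ratio name -> (numerator, denominator)
RATIOS: dict[str, tuple[str, str]] = {
    "CS:ETS": ("CS", "ETS"),
    "COX:ETS": ("COX", "ETS"),
    "CS:LDH": ("CS", "LDH"),
    "COX:LDH": ("COX", "LDH"),
    "CS:COX": ("CS", "COX"),
}


@dataclass
class DuplicateQC:
    accepted: bool
    mean: float | None
    relative_difference: float


def duplicate_qc(pair: tuple[float, float], tolerance: float = 0.10) -> DuplicateQC:
    """Accept a duplicate pair when |a1 − a2| / mean(a1, a2) ≤ tolerance.

    The pair mean is the symmetric denominator for "more than 10% apart".
    A (0, 0) pair has an undefined relative difference and is rejected.
    """
    a1, a2 = pair
    if a1 < 0 or a2 < 0:
        raise ValueError("activities must be non-negative")
    m = 0.5 * (a1 + a2)
    if m == 0.0:
        return DuplicateQC(accepted=False, mean=None, relative_difference=float("inf"))
    rel = abs(a1 - a2) / m
    if rel <= tolerance:
        return DuplicateQC(accepted=True, mean=m, relative_difference=rel)
    return DuplicateQC(accepted=False, mean=None, relative_difference=rel)


@dataclass
class EnzymePanel:
    """One animal's duplicate measurements, accepted means and ratios.

    ``specific`` holds U g⁻¹-protein duplicate pairs, ``total`` (optional)
    U g⁻¹-wet-tissue pairs.  Call :func:`compute_ratios` (or construct via
    the simulator) before reading ``ratios``.
    """

    animal_id: str
    treatment: str
    specific: dict[str, tuple[float, float]]
    total: dict[str, tuple[float, float]] = field(default_factory=dict)
    accepted_specific: dict[str, float] = field(default_factory=dict)
    accepted_total: dict[str, float] = field(default_factory=dict)
    ratios: dict[str, float] = field(default_factory=dict)
    qc_flags: set[str] = field(default_factory=set)


def compute_ratios(panel: EnzymePanel, tolerance: float = 0.10) -> EnzymePanel:
    """Run duplicate QC on every enzyme, then form the five specific-activity
    ratios from the accepted means.

    A rejected enzyme gets a ``duplicate_fail:<enzyme>`` flag and all its
    ratios are left absent; the remaining ratios are still computed (the
    per-analysis exclusion rule).  A zero denominator leaves that ratio
    absent with a ``zero_denominator:<ratio>`` flag.
    """
    for name, pair in panel.specific.items():
        qc = duplicate_qc(pair, tolerance)
        if qc.accepted:
            panel.accepted_specific[name] = qc.mean
        else:
            panel.qc_flags.add(f"duplicate_fail:{name}")
    for name, pair in panel.total.items():
        qc = duplicate_qc(pair, tolerance)
        if qc.accepted:
            panel.accepted_total[name] = qc.mean
        else:
            panel.qc_flags.add(f"duplicate_fail_total:{name}")
    for rname, (num, den) in RATIOS.items():
        if num not in panel.accepted_specific or den not in panel.accepted_specific:
            continue
        d = panel.accepted_specific[den]
        if d == 0.0:
            panel.qc_flags.add(f"zero_denominator:{rname}")
            continue
        panel.ratios[rname] = panel.accepted_specific[num] / d
    return panel
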