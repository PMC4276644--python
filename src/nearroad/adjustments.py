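"""Measurement-driven input adjustments.

Permanent traffic recorders (PTRs) provide measured AADT and commercial
AADT (CAADT) on a subset of links. Three procedures use them: comparing
modeled against measured AADT, a VMT-conserving rescale that shifts
volume from interstates to freeways, and reassigning a link's fleet mix
when its measured diesel share (CAADT/AADT) disagrees with the class
default — which can reclassify HD roadways (and the participants living
near them) to LD. Because dispersion was run at unit emissions, all of
these reuse the stored chi matrix unchanged.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import pandas as pd

from .emissions import FleetMix, diesel_fraction
from .network import Link, PTRRecord, Receptor
from .exposure import classify_receptors

__all__ = [
    "AdjustmentLog",
    "compare_aadt",
    "rescale_aadt",
    "reassign_diesel",
    "relabel_cohorts",
]


@dataclass
class AdjustmentLog:
    """Audit trail of every link and receptor change, with reasons."""

    entries: list[dict] = field(default_factory=list)

    def record(self, kind: str, target: str, old, new, reason: str) -> None:
        self.entries.append(
            {"kind": kind, "target": target, "old": old, "new": new, "reason": reason}
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.entries, columns=["kind", "target", "old", "new", "reason"]
        )

    def report(self) -> str:
        if not self.entries:
            return "no adjustments applied\n"
        lines = [
            f"{e['kind']:>10}  {e['target']:<12} {e['old']!s:>12} -> {e['new']!s:<12} {e['reason']}"
            for e in self.entries
        ]
        return "\n".join(lines) + "\n"


def compare_aadt(links: list[Link], ptrs: list[PTRRecord]) -> pd.DataFrame:
    """Modeled-vs-measured AADT, percent difference per link and year.

    pct_diff = 100 * (model - measured) / measured; positive means the
    travel-demand model overestimates.
    """
    by_id = {l.id: l for l in links}
    rows = []
    for rec in ptrs:
        if rec.link_id not in by_id:
            raise KeyError(f"PTR record references unknown link {rec.link_id!r}")
        if rec.measured_aadt == 0:
            raise ZeroDivisionError(
                f"PTR {rec.link_id!r}/{rec.year}: measured AADT is zero"
            )
        model = by_id[rec.link_id].aadt
        rows.append(
            {
                "link_id": rec.link_id,
                "year": rec.year,
                "model_aadt": model,
                "measured_aadt": rec.measured_aadt,
                "pct_diff": 100.0 * (model - rec.measured_aadt) / rec.measured_aadt,
            }
        )
    return pd.DataFrame(rows)


def rescale_aadt(
    links: list[Link], interstate_factor: float = 0.8
) -> tuple[list[Link], AdjustmentLog]:
    """Scale interstate AADT and redistribute the volume to freeways.

    NFC 11 AADT is multiplied by `interstate_factor`; the removed
    vehicle-meters-traveled are added back uniformly per meter of NFC 12
    roadway, so total network VMT is conserved exactly.
    """
    log = AdjustmentLog()
    out = [copy.deepcopy(l) for l in links]
    if interstate_factor == 1.0:
        return out, log
    interstates = [l for l in out if l.nfc == 11]
    freeways = [l for l in out if l.nfc == 12]
    if interstate_factor < 1.0 and interstates and not freeways:
        raise ValueError("no NFC 12 links available to absorb the removed VMT")
    removed_vmt = sum((1.0 - interstate_factor) * l.aadt * l.length for l in interstates)
    freeway_length = sum(l.length for l in freeways)
    for l in interstates:
        old = l.aadt
        l.aadt = old * interstate_factor
        log.record(
            "aadt", l.id, old, l.aadt,
            f"interstate AADT x {interstate_factor:g} (measured-AADT correction)",
        )
    if freeways and removed_vmt != 0.0:
        increment = removed_vmt / freeway_length
        for l in freeways:
            old = l.aadt
            l.aadt = old + increment
            log.record(
                "aadt", l.id, old, l.aadt,
                "freeway AADT increased to conserve network VMT",
            )
    return out, log


def reassign_diesel(
    links: list[Link],
    ptrs: list[PTRRecord],
    mixes: dict[str, FleetMix],
    study_year: int | None = None,
) -> tuple[list[Link], AdjustmentLog]:
    """Switch measured links to the catalog mix nearest their diesel share.

    The measured diesel share is CAADT/AADT from the traffic recorder
    (commercial volume equated to diesel volume). Ties keep the original
    mix; links without a CAADT measurement are unchanged. AADT is never
    touched here. A link whose mix moves to a lower/higher diesel class
    has its HD/LD designation updated accordingly.
    """
    log = AdjustmentLog()
    out = [copy.deepcopy(l) for l in links]
    by_id = {l.id: l for l in out}
    fractions = {name: diesel_fraction(m) for name, m in mixes.items()}
    for rec in ptrs:
        if study_year is not None and rec.year != study_year:
            continue
        if rec.measured_caadt is None or rec.link_id not in by_id:
            continue
        if rec.measured_caadt > rec.measured_aadt:
            raise ValueError(
                f"PTR {rec.link_id!r}/{rec.year}: CAADT exceeds AADT"
            )
        link = by_id[rec.link_id]
        share = 100.0 * rec.measured_caadt / rec.measured_aadt
        current = link.resolved_mix_name()
        best = min(
            fractions,
            key=lambda name: (abs(fractions[name] - share), name != current),
        )
        if abs(fractions[best] - share) == abs(fractions[current] - share):
            best = current  # ties keep the original assignment
        if best != current:
            link.mix_name = best
            old_group = link.resolved_diesel_group()
            hd_name = max(fractions, key=fractions.get)
            new_group = "HD" if best == hd_name else "LD"
            if old_group is not None and new_group != old_group:
                link.diesel_group = new_group
                log.record(
                    "diesel_group", link.id, old_group, new_group,
                    f"measured diesel share {share:.1f}% nearest mix {best!r}",
                )
            log.record(
                "mix", link.id, current, best,
                f"measured diesel share {share:.1f}% (CAADT/AADT)",
            )
    return out, log


def relabel_cohorts(
    receptors: list[Receptor],
    adjusted_links: list[Link],
    old_labels: pd.DataFrame,
    ht_aadt_min: float = 50000.0,
    near_m: float = 300.0,
    verynear_m: float = 150.0,
) -> tuple[pd.DataFrame, AdjustmentLog]:
    """Re-run cohort classification on adjusted links.

    Receptors that move HTHD -> HTLD keep the dedicated "HD_to_LD" label
    so the reclassified group stays visible in reporting.
    """
    log = AdjustmentLog()
    new = classify_receptors(
        receptors, adjusted_links, ht_aadt_min=ht_aadt_min,
        near_m=near_m, verynear_m=verynear_m,
    )
    old = old_labels.set_index("receptor_id")["label"]
    labels = []
    for row in new.itertuples():
        before = old.get(row.receptor_id, "unassigned")
        after = row.label
        if before == "HTHD" and after == "HTLD":
            after = "HD_to_LD"
        if after != before:
            log.record(
                "cohort", row.receptor_id, before, after,
                "reclassification after link adjustments",
            )
        labels.append(after)
    new = new.assign(label=labels)
    return new, log
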