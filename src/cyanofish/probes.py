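"""Rule-based oligonucleotide FISH probe-set design.

Probe sets for single-molecule mRNA FISH tile the target transcript with
short fluorophore-labeled oligos: each probe is 20 nt, GC content near 50%,
with at least two unprobed bases between adjacent probe sites, and a set
size capped at 48. Selection is a deterministic greedy left-to-right scan:
the first admissible 20-mer window is accepted, then the scan jumps past the
probe plus the minimum gap. Probes are emitted 5'→3' as synthesized, i.e.
the reverse complement of the target window, with the fluorophore at the
3' end recorded as metadata.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from Bio.SeqUtils import gc_fraction

log = logging.getLogger(__name__)

__all__ = ["Probe", "ProbeSet", "ProbeDesignError", "design_probes", "validate_probeset"]

PROBE_LENGTH = 20
MIN_GAP = 2
MAX_PROBES = 48
#: below this count the designer warns (typical published sets are 40-48)
TYPICAL_MIN_PROBES = 40


class ProbeDesignError(ValueError):
    pass


@dataclass
class Probe:
    start: int  # 0-based index of the target window
    sequence: str  # 5'->3' as synthesized (reverse complement of the window)
    gc_percent: float


@dataclass
class ProbeSet:
    target_id: str
    probes: list[Probe]
    fluorophore_label: str = "TAMRA"
    fluorophore_position: str = "3prime"

    def __len__(self) -> int:
        return len(self.probes)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "index": i,
                    "target_start": p.start,
                    "sequence": p.sequence,
                    "gc_percent": p.gc_percent,
                }
                for i, p in enumerate(self.probes)
            ],
            columns=["index", "target_start", "sequence", "gc_percent"],
        )

    def to_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for i, p in enumerate(self.probes):
                fh.write(f">{self.target_id}_probe_{i:02d} start={p.start} "
                         f"gc={p.gc_percent:.1f} label={self.fluorophore_label}\n")
                fh.write(p.sequence + "\n")


def _clean_target(target: str) -> str:
    seq = str(target).strip().upper().replace("U", "T")
    bad = set(seq) - set("ACGT")
    if bad:
        raise ProbeDesignError(f"target contains non-ACGTU characters: {sorted(bad)}")
    return seq


def design_probes(
    target: str,
    gc_window: tuple[float, float] = (45.0, 55.0),
    max_probes: int = MAX_PROBES,
    target_id: str = "target",
    fluorophore_label: str = "TAMRA",
) -> ProbeSet:
    """Design a FISH probe set against one target mRNA sequence.

    Greedy scan: starting at position 0, accept the first 20-nt window whose
    GC content lies in ``gc_window`` (percent, inclusive), then jump
    ``PROBE_LENGTH + MIN_GAP`` positions and continue; stop at the end of the
    sequence or at ``max_probes``. Deterministic in the target.

    Raises
    ------
    ProbeDesignError
        If the target is shorter than 22 nt, contains letters outside
        ACGTU, or has no admissible window (the error reports the GC
        distribution of all windows to guide a wider window choice).
    """
    seq = _clean_target(target)
    if len(seq) < PROBE_LENGTH + MIN_GAP:
        raise ProbeDesignError(
            f"target length {len(seq)} < {PROBE_LENGTH + MIN_GAP}"
        )
    lo, hi = gc_window
    probes: list[Probe] = []
    i = 0
    while i + PROBE_LENGTH <= len(seq) and len(probes) < max_probes:
        window = seq[i : i + PROBE_LENGTH]
        gc = 100.0 * gc_fraction(Seq(window))
        if lo <= gc <= hi:
            probes.append(
                Probe(
                    start=i,
                    sequence=str(Seq(window).reverse_complement()),
                    gc_percent=gc,
                )
            )
            i += PROBE_LENGTH + MIN_GAP
        else:
            i += 1
    if not probes:
        gcs = [
            100.0 * gc_fraction(Seq(seq[j : j + PROBE_LENGTH]))
            for j in range(len(seq) - PROBE_LENGTH + 1)
        ]
        raise ProbeDesignError(
            f"no 20-mer window with GC in [{lo}, {hi}]%; window GC range "
            f"{min(gcs):.1f}-{max(gcs):.1f}%, median {float(np.median(gcs)):.1f}%"
        )
    if len(probes) < TYPICAL_MIN_PROBES:
        log.warning(
            "probe set for %s has %d probes (< %d typical minimum)",
            target_id, len(probes), TYPICAL_MIN_PROBES,
        )
    return ProbeSet(
        target_id=target_id, probes=probes, fluorophore_label=fluorophore_label
    )


@dataclass
class ValidationReport:
    violations: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations


def validate_probeset(probeset: ProbeSet, target: str) -> ValidationReport:
    """Check every probe-set invariant against the target sequence.

    Verifies probe length, inter-probe spacing (>= 2 nt between sites),
    set-size cap, and that each probe is the reverse complement of its
    target window. Violations are reported, never raised.
    """
    seq = _clean_target(target)
    report = ValidationReport()
    if len(probeset.probes) > MAX_PROBES:
        report.violations.append(
            f"set size {len(probeset.probes)} exceeds cap {MAX_PROBES}"
        )
    prev_end = None
    for i, p in enumerate(probeset.probes):
        if len(p.sequence) != PROBE_LENGTH:
            report.violations.append(
                f"probe {i}: length {len(p.sequence)} != {PROBE_LENGTH}"
            )
        if p.start < 0 or p.start + PROBE_LENGTH > len(seq):
            report.violations.append(f"probe {i}: window outside target")
            continue
        window = seq[p.start : p.start + PROBE_LENGTH]
        if p.sequence != str(Seq(window).reverse_complement()):
            report.violations.append(
                f"probe {i}: sequence is not the reverse complement of its window"
            )
        if prev_end is not None and p.start < prev_end + MIN_GAP:
            report.violations.append(
                f"probe {i}: starts {p.start}, needs >= {prev_end + MIN_GAP} "
                f"({MIN_GAP}-nt gap)"
            )
        prev_end = p.start + PROBE_LENGTH
    return report
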