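"""Built-in PCR primer pair design for probe amplicons.

One optimized primer pair is produced per probe target.  Candidates are
scored on length, nearest-neighbor melting temperature, GC content,
homopolymer runs, and self/pair complementarity; the pair minimizing the
summed penalties (plus the Tm difference) wins, deterministically.  Both
primers are finally extended with a 5' restriction-site linker (lowercase
``atcgat``, the ClaI site) so clones can be screened by restriction digest.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional

from fishprobes.alignment import revcomp
from fishprobes.targets import ProbeTarget

# Unified nearest-neighbor parameters (Allawi & SantaLucia 1997):
# delta-H kcal/mol, delta-S cal/(mol*K) per propagation step, keyed by the
# top-strand dinucleotide (the complementary step shares the same values).
_NN: dict[str, tuple[float, float]] = {
    "AA": (-7.9, -22.2), "TT": (-7.9, -22.2),
    "AT": (-7.2, -20.4),
    "TA": (-7.2, -21.3),
    "CA": (-8.5, -22.7), "TG": (-8.5, -22.7),
    "GT": (-8.4, -22.4), "AC": (-8.4, -22.4),
    "CT": (-7.8, -21.0), "AG": (-7.8, -21.0),
    "GA": (-8.2, -22.2), "TC": (-8.2, -22.2),
    "CG": (-10.6, -27.2),
    "GC": (-9.8, -24.4),
    "GG": (-8.0, -19.9), "CC": (-8.0, -19.9),
}
_INIT_AT = (2.3, 4.1)
_INIT_GC = (0.1, -2.8)
_R = 1.987  # gas constant, cal/(mol*K)


class PrimerDesignError(RuntimeError):
    """No feasible primer pair exists for a target."""


def melting_temperature(
    seq: str, monovalent_mM: float = 50.0, primer_nM: float = 50.0
) -> float:
    """Nearest-neighbor duplex melting temperature in Celsius.

    Unified NN enthalpies/entropies with terminal initiation terms, the
    entropic monovalent-salt correction 0.368*(N-1)*ln[Na+], and a total
    strand concentration treated as two equal non-self-complementary
    strands (CT/4 in the denominator).
    """
    seq = seq.upper()
    if len(seq) < 8:
        raise ValueError("sequence too short for NN melting temperature (< 8 nt)")
    if any(c not in "ACGT" for c in seq):
        raise ValueError("melting temperature requires an A/C/G/T-only sequence")
    dh = ds = 0.0
    for i in range(len(seq) - 1):
        h, s = _NN[seq[i : i + 2]]
        dh += h
        ds += s
    for end in (seq[0], seq[-1]):
        h, s = _INIT_AT if end in "AT" else _INIT_GC
        dh += h
        ds += s
    ds += 0.368 * (len(seq) - 1) * math.log(monovalent_mM / 1000.0)
    ct = primer_nM * 1e-9 / 4.0
    return 1000.0 * dh / (ds + _R * math.log(ct)) - 273.15


@dataclass(frozen=True)
class PrimerConstraints:
    """Hard windows and optima for primer scoring (engine-style defaults)."""

    len_min: int = 18
    len_opt: int = 20
    len_max: int = 27
    tm_min: float = 57.0
    tm_opt: float = 60.0
    tm_max: float = 63.0
    max_tm_diff: float = 3.0
    gc_min: float = 0.2
    gc_max: float = 0.8
    max_run: int = 4
    max_self_any: int = 8
    max_pair_any: int = 8
    monovalent_mm: float = 50.0
    dna_nm: float = 50.0
    weight_len: float = 1.0
    weight_tm: float = 1.0

    def __post_init__(self) -> None:
        if not self.len_min <= self.len_opt <= self.len_max:
            raise ValueError("require len_min <= len_opt <= len_max")
        if not self.tm_min <= self.tm_opt <= self.tm_max:
            raise ValueError("require tm_min <= tm_opt <= tm_max")
        if not 0 <= self.gc_min <= self.gc_max <= 1:
            raise ValueError("require 0 <= gc_min <= gc_max <= 1")


@dataclass(frozen=True)
class Primer:
    """A primer with optional 5' linker; Tm/GC refer to the core only."""

    core_seq: str
    strand: str
    start: int  # query coordinate of the core 5' end
    tm: float
    gc: float
    penalty: float
    linker: str = ""

    @property
    def full_seq(self) -> str:
        return self.linker + self.core_seq


@dataclass(frozen=True)
class PrimerPair:
    forward: Primer
    reverse: Primer
    product_interval: tuple[int, int]
    pair_penalty: float

    @property
    def product_len(self) -> int:
        return self.product_interval[1] - self.product_interval[0]


def gc_fraction(seq: str) -> float:
    seq = seq.upper()
    return (seq.count("G") + seq.count("C")) / len(seq)


def max_homopolymer_run(seq: str) -> int:
    best = run = 1
    for a, b in zip(seq, seq[1:]):
        run = run + 1 if a == b else 1
        best = max(best, run)
    return best


def pair_complementarity(a: str, b: str) -> int:
    """Best ungapped antiparallel complementarity: the maximum number of
    Watson-Crick pairings over all relative offsets of the two primers."""
    y = revcomp(b.upper())
    a = a.upper()
    best = 0
    for shift in range(-(len(y) - 1), len(a)):
        count = 0
        for i in range(max(0, shift), min(len(a), shift + len(y))):
            if a[i] == y[i - shift]:
                count += 1
        best = max(best, count)
    return best


def self_complementarity(seq: str) -> int:
    return pair_complementarity(seq, seq)


def primer_feasibility(seq: str, constraints: PrimerConstraints) -> Optional[float]:
    """Penalty of a candidate primer, or None if a hard bound rejects it.

    Hard bounds: length and Tm windows, GC window, homopolymer runs longer
    than max_run, self-complementarity above max_self_any.  The penalty is
    the weighted absolute deviation from the length and Tm optima.
    """
    seq = seq.upper()
    n = len(seq)
    if n < constraints.len_min or n > constraints.len_max:
        return None
    if any(c not in "ACGT" for c in seq):
        return None
    if max_homopolymer_run(seq) > constraints.max_run:
        return None
    gc = gc_fraction(seq)
    if not constraints.gc_min <= gc <= constraints.gc_max:
        return None
    tm = melting_temperature(seq, constraints.monovalent_mm, constraints.dna_nm)
    if not constraints.tm_min <= tm <= constraints.tm_max:
        return None
    if self_complementarity(seq) > constraints.max_self_any:
        return None
    return (
        constraints.weight_len * abs(n - constraints.len_opt)
        + constraints.weight_tm * abs(tm - constraints.tm_opt)
    )


def _forward_candidates(template, t0, t1, margin, constraints):
    out = []
    for f in range(t0, min(t0 + margin, t1)):
        for length in range(constraints.len_min, constraints.len_max + 1):
            if f + length > t1:
                break
            core = template[f : f + length]
            pen = primer_feasibility(core, constraints)
            if pen is None:
                continue
            out.append(
                Primer(
                    core_seq=core, strand="+", start=f,
                    tm=melting_temperature(core, constraints.monovalent_mm, constraints.dna_nm),
                    gc=gc_fraction(core), penalty=pen,
                )
            )
    out.sort(key=lambda p: (p.penalty, p.start, len(p.core_seq)))
    return out


def _reverse_candidates(template, t0, t1, margin, constraints):
    out = []
    for r in range(t1 - 1, max(t1 - margin, t0) - 1, -1):
        for length in range(constraints.len_min, constraints.len_max + 1):
            if r - length + 1 < t0:
                break
            core = revcomp(template[r - length + 1 : r + 1])
            pen = primer_feasibility(core, constraints)
            if pen is None:
                continue
            out.append(
                Primer(
                    core_seq=core, strand="-", start=r,
                    tm=melting_temperature(core, constraints.monovalent_mm, constraints.dna_nm),
                    gc=gc_fraction(core), penalty=pen,
                )
            )
    out.sort(key=lambda p: (p.penalty, -p.start, len(p.core_seq)))
    return out


def design_pair(
    template: str,
    target: ProbeTarget,
    constraints: PrimerConstraints = PrimerConstraints(),
    margin: int = 200,
) -> PrimerPair:
    """Optimal primer pair for a probe target under the builtin engine.

    Forward 5' ends are searched within ``margin`` bases of the target
    start (inside the target), reverse 5' ends within ``margin`` bases of
    the target end.  A pair is rejected outright when the Tm difference
    exceeds max_tm_diff or the pair complementarity exceeds max_pair_any;
    among the rest the pair minimizing forward + reverse penalty + Tm
    difference wins, ties going to the smaller product, then the leftmost
    forward primer.  The product never extends beyond the target interval.
    """
    t0, t1 = target.interval
    fwd = _forward_candidates(template, t0, t1, margin, constraints)
    rev = _reverse_candidates(template, t0, t1, margin, constraints)
    if not fwd or not rev:
        raise PrimerDesignError(
            f"no feasible primer pair for target {target.label or target.interval}"
        )
    best = None  # (total, product_len, f_start, pair)
    min_rpen = rev[0].penalty
    for f in fwd:
        if best is not None and f.penalty + min_rpen > best[0]:
            break
        f_end = f.start + len(f.core_seq)
        for r in rev:
            if best is not None and f.penalty + r.penalty > best[0]:
                break
            if r.start - len(r.core_seq) + 1 < f_end:
                continue  # primers would overlap
            tm_diff = abs(f.tm - r.tm)
            if tm_diff > constraints.max_tm_diff:
                continue
            total = f.penalty + r.penalty + tm_diff
            product_len = r.start + 1 - f.start
            key = (total, product_len, f.start)
            if best is not None and key >= (best[0], best[1], best[2]):
                continue
            if pair_complementarity(f.core_seq, r.core_seq) > constraints.max_pair_any:
                continue
            best = (total, product_len, f.start,
                    PrimerPair(forward=f, reverse=r,
                               product_interval=(f.start, r.start + 1),
                               pair_penalty=total))
    if best is None:
        raise PrimerDesignError(
            f"no feasible primer pair for target {target.label or target.interval}"
        )
    return best[3]


def extend_five_prime(pair: PrimerPair, linker: str = "atcgat") -> PrimerPair:
    """Prefix both primers' full sequences with a 5' linker (lowercase).

    The core sequence, coordinates and Tm are unchanged — the linker is
    unpaired in early PCR cycles and serves only for later clone screening.
    Applying a linker twice is an error.
    """
    if any(c not in "ACGTacgt" for c in linker):
        raise ValueError(f"linker {linker!r} is not a DNA string")
    if pair.forward.linker or pair.reverse.linker:
        raise ValueError("already extended: primers carry a 5' linker")
    linker = linker.lower()
    return replace(
        pair,
        forward=replace(pair.forward, linker=linker),
        reverse=replace(pair.reverse, linker=linker),
    )
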