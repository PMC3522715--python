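"""Serialization: FASTA, BED tracks, key=value config, report, track figure.

BED output is 0-based half-open; the human-readable report and primer
table print 1-based inclusive coordinates in the chrom:start-end style
genome browsers and Ensembl use.
"""

from __future__ import annotations

import dataclasses
import re
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
from Bio import SeqIO

from fishprobes.alignment import SequenceRecord
from fishprobes.classify import Label, Region, SimilarityMask
from fishprobes.pipeline import PipelineResult
from fishprobes.targets import DesignConfig, ProbeTarget

_ORIGIN_RE = re.compile(r"([\w.]+):(\d+)-(\d+)")

IUPAC_FASTA = frozenset("ACGTNRYSWKMBDHV")


def read_fasta(path: Union[str, Path]) -> list[SequenceRecord]:
    """Read a (multi-)FASTA file into SequenceRecords.

    Sequences are uppercased; ambiguity codes other than N are rejected
    up front (the design pipeline is defined over A/C/G/T/N).  A
    ``chrom:start-end`` token in the description becomes the record's
    genomic origin when its span matches the sequence length.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"{path}: no FASTA records")
    out: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in records:
        if rec.id in seen:
            raise ValueError(f"{path}: duplicate record id {rec.id!r}")
        seen.add(rec.id)
        seq = str(rec.seq).upper()
        if not seq:
            raise ValueError(f"{path}: record {rec.id!r} has no sequence")
        bad = set(seq) - IUPAC_FASTA
        if bad:
            raise ValueError(f"{path}: record {rec.id!r} has non-IUPAC characters {sorted(bad)}")
        seq = re.sub("[RYSWKMBDHV]", "N", seq)  # rare ambiguity codes degrade to N
        origin = None
        m = _ORIGIN_RE.search(rec.description)
        if m:
            chrom, start, end = m.group(1), int(m.group(2)), int(m.group(3))
            if end - start + 1 == len(seq):
                origin = (chrom, start, end)
        out.append(SequenceRecord(id=rec.id, seq=seq, origin=origin))
    return out


def write_fasta(records: Sequence[tuple[str, str]], path: Union[str, Path]) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


# --- BED ------------------------------------------------------------------


def write_bed(
    items: Sequence[Union[Region, ProbeTarget]],
    path: Union[str, Path],
    track_name: str,
    chrom: str,
) -> None:
    """Write regions as BED6 or probe targets as BED12.

    Targets span their binding sites: the record interval is the envelope,
    the blocks are the individual binding sites, and thickStart/thickEnd
    mark the amplicon itself.
    """
    regions = [i for i in items if isinstance(i, Region)]
    by_label: dict[str, list[Region]] = {}
    for r in regions:
        by_label.setdefault(r.label, []).append(r)
    for label, rs in by_label.items():
        rs = sorted(rs, key=lambda r: r.start)
        for a, b in zip(rs[:-1], rs[1:]):
            if b.start < a.end:
                raise ValueError(
                    f"overlapping {label} regions [{a.start},{a.end}) and "
                    f"[{b.start},{b.end}) violate maximality"
                )
    with open(path, "w") as fh:
        fh.write(f'track name="{track_name}"\n')
        for item in sorted(items, key=lambda i: i.start):
            if isinstance(item, Region):
                fh.write(f"{chrom}\t{item.start}\t{item.end}\t{item.label}\t0\t.\n")
            else:
                blocks = sorted(item.binding_sites)
                b0, b1 = blocks[0][0], blocks[-1][1]
                sizes = ",".join(str(e - s) for s, e in blocks)
                starts = ",".join(str(s - b0) for s, e in blocks)
                fh.write(
                    f"{chrom}\t{b0}\t{b1}\t{item.label or item.kind}\t0\t.\t"
                    f"{item.start}\t{item.end}\t0\t{len(blocks)}\t{sizes}\t{starts}\n"
                )


def read_bed(path: Union[str, Path]) -> list[dict]:
    """Minimal reader for the BED dialect this package writes (track lines
    skipped; BED12 blocks expanded into absolute intervals)."""
    out: list[dict] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "#", "browser")):
                continue
            f = line.split("\t")
            rec = {"chrom": f[0], "start": int(f[1]), "end": int(f[2]), "name": f[3]}
            if len(f) >= 12:
                n = int(f[9])
                sizes = [int(x) for x in f[10].rstrip(",").split(",")]
                starts = [int(x) for x in f[11].rstrip(",").split(",")]
                if len(sizes) != n or len(starts) != n:
                    raise ValueError(f"{path}: blockCount mismatch in {line!r}")
                rec["thick"] = (int(f[6]), int(f[7]))
                rec["blocks"] = [
                    (rec["start"] + st, rec["start"] + st + sz)
                    for st, sz in zip(starts, sizes)
                ]
            out.append(rec)
    return out


def mask_to_regions(mask: SimilarityMask) -> list[Region]:
    from fishprobes.classify import extract_regions

    regions: list[Region] = []
    for lab in Label:
        regions.extend(extract_regions(mask, lab))
    return sorted(regions, key=lambda r: r.start)


# --- configuration --------------------------------------------------------

_CONFIG_DOC = {
    "min_bits": "minimum alignment bit score for a similarity hit (bits)",
    "word_size": "exact-match seed length of the aligner (nt)",
    "match_reward": "aligner match reward",
    "mismatch_penalty": "aligner mismatch penalty (negative)",
    "karlin_lambda": "Karlin-Altschul lambda for the scoring scheme",
    "karlin_k": "Karlin-Altschul K for the scoring scheme",
    "xdrop": "X-drop termination threshold for ungapped extension",
    "min_unique_len": "unique blocks must exceed this length (bp)",
    "max_gap": "permissible gap inside nearly contiguous similar regions (bp)",
    "amplicon_min": "minimum PCR amplicon length (bp)",
    "amplicon_max": "maximum PCR amplicon length (bp)",
    "min_gain": "stop selecting repetitive targets below this marginal binding gain (bp)",
    "forbidden_sites": "comma-separated restriction sites that must not occur in amplicons",
    "site_mode": "verify: report forbidden sites; enforce: shift/split amplicons around them",
    "linker": "5' linker prepended to both primers (lowercase in reports)",
    "primer_len_min": "minimum primer length (nt)",
    "primer_len_opt": "optimal primer length (nt)",
    "primer_len_max": "maximum primer length (nt)",
    "primer_tm_min": "minimum primer melting temperature (C)",
    "primer_tm_opt": "optimal primer melting temperature (C)",
    "primer_tm_max": "maximum primer melting temperature (C)",
    "primer_max_tm_diff": "maximum Tm difference within a pair (C)",
    "primer_gc_min": "minimum primer GC fraction",
    "primer_gc_max": "maximum primer GC fraction",
    "primer_max_run": "maximum homopolymer run in a primer (nt)",
    "primer_max_self_any": "maximum self-complementarity score",
    "primer_max_pair_any": "maximum pair complementarity score",
    "primer_search_margin": "primer 5' ends searched this far inside each target end (bp)",
    "primer_monovalent_mm": "monovalent cation concentration for Tm (mM)",
    "primer_dna_nm": "primer concentration for Tm (nM)",
    "plot_width": "track figure width (inches)",
    "plot_height": "track figure height (inches)",
    "plot_dpi": "track figure resolution (dpi)",
}


def load_config(path: Union[str, Path]) -> DesignConfig:
    """Parse a commented key=value configuration file into a DesignConfig.

    Unknown keys are an error (listed); missing keys fall back to the
    documented defaults.
    """
    fields = {f.name: f for f in dataclasses.fields(DesignConfig)}
    values: dict = {}
    unknown: list[str] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected key=value, got {raw.rstrip()!r}")
            key, _, val = line.partition("=")
            key, val = key.strip(), val.strip()
            if key not in fields:
                unknown.append(key)
                continue
            values[key] = _coerce(key, val, fields[key].type)
    if unknown:
        raise ValueError(f"{path}: unknown configuration keys: {', '.join(sorted(unknown))}")
    return DesignConfig(**values)


def _coerce(key: str, val: str, ftype: str):
    try:
        if key == "forbidden_sites":
            return tuple(s.strip().upper() for s in val.split(",") if s.strip())
        if "int" in str(ftype):
            return int(val)
        if "float" in str(ftype):
            return float(val)
        return val
    except ValueError:
        raise ValueError(f"configuration key {key!r}: cannot parse {val!r}") from None


def write_effective_config(cfg: DesignConfig, path: Union[str, Path]) -> None:
    """Write the fully-commented effective configuration back out."""
    with open(path, "w") as fh:
        fh.write("# effective configuration (every parameter, with defaults applied)\n")
        for f in dataclasses.fields(cfg):
            val = getattr(cfg, f.name)
            if isinstance(val, tuple):
                val = ",".join(val)
            doc = _CONFIG_DOC.get(f.name, "")
            fh.write(f"# {doc}\n{f.name} = {val}\n")


# --- report ---------------------------------------------------------------


def _fmt_1based(start: int, end: int) -> str:
    return f"{start + 1}-{end}"


def primer_table_rows(result: PipelineResult) -> list[dict]:
    rows = []
    for t in result.targets:
        pair = result.primer_pairs[t.label]
        s, e = pair.product_interval
        rows.append(
            {
                "label": t.label,
                "kind": t.kind,
                "forward": pair.forward.full_seq,
                "reverse": pair.reverse.full_seq,
                "forward_tm": f"{pair.forward.tm:.2f}",
                "reverse_tm": f"{pair.reverse.tm:.2f}",
                "forward_gc": f"{pair.forward.gc:.3f}",
                "reverse_gc": f"{pair.reverse.gc:.3f}",
                "product_len": str(pair.product_len),
                "product_coords": _fmt_1based(s, e),
                "cumulative_binding": str(t.cumulative_binding),
            }
        )
    return rows


def write_primer_table(result: PipelineResult, path: Union[str, Path]) -> None:
    rows = primer_table_rows(result)
    cols = [
        "label", "kind", "forward", "reverse", "forward_tm", "reverse_tm",
        "forward_gc", "reverse_gc", "product_len", "product_coords",
        "cumulative_binding",
    ]
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for r in rows:
            fh.write("\t".join(r[c] for c in cols) + "\n")


def write_report(result: PipelineResult, path: Union[str, Path]) -> None:
    """Human-readable run report: config echo, mask summary, regions,
    targets with cumulative binding, primers, and the dropped-item log."""
    cfg = result.config
    counts = result.mask.counts()
    lines: list[str] = []
    lines.append(f"query: {result.query.id} ({len(result.query)} bp)")
    locus = result.self_locus
    lines.append(
        f"self locus: {locus.subject_id}:{_fmt_1based(locus.start, locus.end)} ({locus.source})"
    )
    lines.append("")
    lines.append("[configuration]")
    for f in dataclasses.fields(cfg):
        val = getattr(cfg, f.name)
        if isinstance(val, tuple):
            val = ",".join(val)
        lines.append(f"{f.name} = {val}")
    lines.append("")
    lines.append("[similarity mask]")
    total = sum(counts.values())
    for name, n in counts.items():
        lines.append(f"{name}: {n} bp ({100.0 * n / total:.1f}%)")
    lines.append("")
    lines.append("[unique blocks > {} bp]".format(cfg.min_unique_len))
    for r in result.unique_blocks:
        lines.append(f"{result.query.id}:{_fmt_1based(r.start, r.end)} ({r.length} bp)")
    lines.append("")
    lines.append("[similar blocks (max gap {} bp)]".format(cfg.max_gap))
    for r in result.similar_blocks:
        lines.append(f"{result.query.id}:{_fmt_1based(r.start, r.end)} ({r.length} bp)")
    lines.append("")
    lines.append("[probe targets]")
    total_len = result.total_probe_length
    total_bind = result.total_binding_length
    for t in result.targets:
        lines.append(
            f"{t.label}\t{t.kind}\t{result.query.id}:{_fmt_1based(t.start, t.end)}"
            f"\t{t.length} bp\tbinds {t.cumulative_binding} bp"
        )
    lines.append(
        f"combined probe length {total_len / 1000.0:.1f} kb, "
        f"cumulative binding {total_bind / 1000.0:.1f} kb"
    )
    lines.append("")
    lines.append("[primer pairs]")
    for r in primer_table_rows(result):
        lines.append(
            f"{r['label']}\t{r['forward']}\t{r['reverse']}\t{r['product_len']} bp"
            f"\t{result.query.id}:{r['product_coords']}"
        )
    lines.append("")
    lines.append("[skipped/dropped]")
    for note in result.dropped:
        lines.append(note)
    if not result.dropped:
        lines.append("(none)")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


# --- figure ---------------------------------------------------------------

_LABEL_COLORS = {
    Label.UNIQUE: "#ffffff",
    Label.SIMILAR_GLOBAL: "#b0b0b0",
    Label.SIMILAR_LOCAL: "#00e5e5",
}


def render_tracks(
    mask: SimilarityMask,
    targets: Sequence[ProbeTarget],
    path: Union[str, Path],
    cfg: Optional[DesignConfig] = None,
    genes: Optional[Sequence[Region]] = None,
) -> None:
    """Render the classification background with probe bars above it.

    White = unique, gray = globally similar, cyan = locally repetitive;
    single-copy probes are red bars, repetitive probes green with their
    binding sites as adjacent filled bars.  Output is deterministic for
    fixed input.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    cfg = cfg or DesignConfig()
    n = len(mask)
    fig, ax = plt.subplots(figsize=(cfg.plot_width, cfg.plot_height))
    from fishprobes.classify import extract_regions

    for lab in Label:
        for r in extract_regions(mask, lab):
            ax.axvspan(r.start, r.end, ymin=0.0, ymax=0.45, color=_LABEL_COLORS[lab])
    for t in sorted(targets, key=lambda t: t.start):
        if t.kind == "single_copy":
            ax.plot([t.start, t.end], [0.6, 0.6], color="#cc0000", lw=6, solid_capstyle="butt")
            if t.label:
                ax.text((t.start + t.end) / 2, 0.66, t.label, ha="center", fontsize=7)
        else:
            for s, e in t.binding_sites:
                ax.fill_between([s, e], 0.52, 0.56, color="#00a000")
            ax.plot([t.start, t.end], [0.8, 0.8], color="#00a000", lw=6, solid_capstyle="butt")
            if t.label:
                ax.text((t.start + t.end) / 2, 0.86, t.label, ha="center", fontsize=7)
    if genes:
        for g in genes:
            ax.plot([g.start, g.end], [0.95, 0.95], color="#555555", lw=3)
            ax.text((g.start + g.end) / 2, 0.97, g.label, ha="center", fontsize=6)
    ax.set_xlim(0, n)
    ax.set_ylim(0, 1.05)
    ax.set_yticks([])
    ax.set_xlabel(f"{mask.query_id} position (bp)")
    fig.tight_layout()
    fig.savefig(str(path), dpi=cfg.plot_dpi, metadata={"Software": None})
    plt.close(fig)
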