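"""End-to-end orchestration and paper-style summary artifacts.

The pipeline composes the stages — extract, features, discover, classify,
(ortho), (pap), report — writing TSVs and a manifest of sha256 checksums so
reruns with the same config/seed can be verified byte-identical.
"""
from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from . import io as iomod
from . import ortho, pap
from .classify import ClassifierConfig, classify_all, summarize_classes
from .discovery import discover_families, detect_nested, scan_remnants
from .features import boundary_gc_profile, splice_profile
from .model import AnnotationSet

log = logging.getLogger("intronscape")


@dataclass
class PipelineConfig:
    fasta: str
    gff3: str
    out_dir: str
    classifier: ClassifierConfig = field(default_factory=ClassifierConfig)
    fasta_b: Optional[str] = None
    gff3_b: Optional[str] = None
    fragments_fasta: Optional[str] = None
    min_identity: float = 70.0
    min_coverage: float = 80.0
    min_family_size: int = 3
    remnant_min_identity: float = 65.0
    remnant_min_len: int = 40
    scan_remnants: bool = False  # full-genome scan is the costly opt-in stage
    seed: int = 0


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def size_histogram(a: AnnotationSet, bin_nt: int = 5, max_len: int = 600) -> pd.DataFrame:
    """Per-class intron-size histogram: counts per [k*bin, (k+1)*bin) bin.

    Lengths strictly greater than ``max_len`` are excluded from the bins and
    tallied separately (one ``excluded`` row per class)."""
    per_class: dict[str, list[int]] = {}
    for i in a.introns:
        cls = "ie" if i.class_label.startswith("ie") else i.class_label
        per_class.setdefault(cls, []).append(i.length)
    out = []
    for cls in sorted(per_class):
        lengths = per_class[cls]
        excluded = sum(1 for L in lengths if L > max_len)
        kept = [L for L in lengths if L <= max_len]
        counts: dict[int, int] = {}
        for L in kept:
            b = (L // bin_nt) * bin_nt
            counts[b] = counts.get(b, 0) + 1
        for b in sorted(counts):
            out.append({"class": cls, "bin_start": b, "bin_end": b + bin_nt, "count": counts[b]})
        out.append({"class": cls, "bin_start": -1, "bin_end": -1, "count": excluded})
    return pd.DataFrame(out, columns=["class", "bin_start", "bin_end", "count"])


def density_track(a: AnnotationSet, window: int = 10_000) -> pd.DataFrame:
    """Per-window GC% and per-class intron counts (bedGraph-style long table)."""
    if window <= 0:
        raise ValueError("window must be positive")
    rows = []
    for sid, rec in a.sequences.items():
        n_win = (rec.length + window - 1) // window
        gc = np.zeros(n_win)
        for w in range(n_win):
            chunk = rec.seq[w * window : (w + 1) * window]
            g = chunk.count("G") + chunk.count("C")
            at = chunk.count("A") + chunk.count("T")
            gc[w] = 100.0 * g / (g + at) if g + at else np.nan
        counts: dict[tuple[int, str], int] = {}
        for i in a.introns:
            if i.seq_id != sid:
                continue
            cls = "ie" if i.class_label.startswith("ie") else i.class_label
            w = i.start // window
            counts[(w, cls)] = counts.get((w, cls), 0) + 1
        classes = sorted({c for (_w, c) in counts} | {"canonical"})
        for w in range(n_win):
            for cls in classes:
                rows.append(
                    {
                        "seq_id": sid,
                        "start": w * window,
                        "end": min((w + 1) * window, rec.length),
                        "class": cls,
                        "count": counts.get((w, cls), 0),
                        "gc_percent": round(gc[w], 4),
                    }
                )
    return pd.DataFrame(rows)


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run every configured stage; returns the manifest dict (also written
    to ``manifest.json``). Any stage error aborts with the stage name."""
    os.makedirs(cfg.out_dir, exist_ok=True)
    manifest: dict = {"stages": [], "files": {}, "seed": cfg.seed}
    stage = "load"
    try:
        a = iomod.load_annotation(cfg.fasta, cfg.gff3)
        stage = "extract"
        iomod.extract_introns(a)
        manifest["stages"].append({"stage": stage, "n_introns": len(a.introns)})
        stage = "discover"
        families, singletons, edges = discover_families(
            a,
            min_identity=cfg.min_identity,
            min_coverage=cfg.min_coverage,
            min_family_size=cfg.min_family_size,
        )
        membership = {m: f.id for f in families for m in f.members}
        manifest["stages"].append(
            {"stage": stage, "n_families": len(families), "n_singletons": len(singletons)}
        )
        stage = "classify"
        classify_all(a, membership, cfg.classifier)
        summary = summarize_classes(a)
        stage = "features"
        donor = splice_profile(a, a.introns, side="donor")
        acceptor = splice_profile(a, a.introns, side="acceptor")
        gcp_rows = []
        for cls in sorted({("ie" if i.class_label.startswith("ie") else i.class_label) for i in a.introns}):
            sub = [i for i in a.introns if ("ie" if i.class_label.startswith("ie") else i.class_label) == cls]
            prof = boundary_gc_profile(sub, a)
            for track, arr in prof.mean_gc.items():
                for pos, (m, n) in enumerate(zip(arr, prof.n_per_position[track])):
                    if n > 0:
                        gcp_rows.append(
                            {"class": cls, "track": track, "position": pos,
                             "mean_gc": round(float(m), 4), "n": int(n)}
                        )
        stage = "write"
        paths = iomod.write_tables(a, cfg.out_dir)
        summary.to_csv(os.path.join(cfg.out_dir, "class_summary.tsv"), sep="\t", index=False)
        size_histogram(a).to_csv(os.path.join(cfg.out_dir, "size_histogram.tsv"), sep="\t", index=False)
        density_track(a).to_csv(os.path.join(cfg.out_dir, "density_track.tsv"), sep="\t", index=False)
        pd.DataFrame(gcp_rows).to_csv(os.path.join(cfg.out_dir, "boundary_gc.tsv"), sep="\t", index=False)
        _profile_to_tsv(donor, os.path.join(cfg.out_dir, "splice_profile_donor.tsv"))
        _profile_to_tsv(acceptor, os.path.join(cfg.out_dir, "splice_profile_acceptor.tsv"))
        fam_rows = [
            {"family_id": f.id, "size": f.size, "consensus_len": len(f.consensus),
             "n_blocks": len(f.motif_blocks), "members": ",".join(f.members)}
            for f in families
        ]
        pd.DataFrame(fam_rows, columns=["family_id", "size", "consensus_len", "n_blocks", "members"]).to_csv(
            os.path.join(cfg.out_dir, "families.tsv"), sep="\t", index=False
        )
        iomod.write_fasta(
            ((f.id, f.consensus) for f in families),
            os.path.join(cfg.out_dir, "family_consensus.fa"),
        )
        if cfg.scan_remnants and families:
            stage = "remnants"
            hits = scan_remnants(a, families, cfg.remnant_min_identity, cfg.remnant_min_len)
            pd.DataFrame(
                [{"seq_id": h.seq_id, "start": h.start, "end": h.end, "strand": h.strand,
                  "family_id": h.family_id, "identity": round(h.identity, 2),
                  "matched_block": h.matched_block, "context": h.context} for h in hits]
            ).to_csv(os.path.join(cfg.out_dir, "remnants.tsv"), sep="\t", index=False)
            nested = detect_nested(a, families)
            pd.DataFrame(
                [{"outer_intron_id": n.outer_intron_id, "inner_family_id": n.inner_family_id,
                  "inner_start": n.inner_interval[0], "inner_end": n.inner_interval[1],
                  "kind": n.kind} for n in nested]
            ).to_csv(os.path.join(cfg.out_dir, "nested.tsv"), sep="\t", index=False)
        if cfg.fasta_b and cfg.gff3_b:
            stage = "ortho"
            b = iomod.load_annotation(cfg.fasta_b, cfg.gff3_b)
            iomod.extract_introns(b)
            fams_b, _, _ = discover_families(
                b, min_identity=cfg.min_identity, min_coverage=cfg.min_coverage,
                min_family_size=cfg.min_family_size,
            )
            classify_all(b, {m: f.id for f in fams_b for m in f.members}, cfg.classifier)
            pairs = ortho.build_pairs(a, b)
            report = ortho.shared_position_report(pairs)
            report.per_class.to_csv(os.path.join(cfg.out_dir, "shared_positions.tsv"), sep="\t", index=False)
            report.cross_class.to_csv(os.path.join(cfg.out_dir, "cross_class.tsv"), sep="\t", index=False)
        if cfg.fragments_fasta:
            stage = "pap"
            if not os.path.exists(cfg.fragments_fasta):
                raise FileNotFoundError(f"fragments path missing: {cfg.fragments_fasta}")
            frecs = iomod.read_fasta(cfg.fragments_fasta)
            idx = pap.build_seed_index(a)
            alns = []
            for fid, rec in frecs.items():
                alns.extend(pap.align_fragment(pap.Fragment(id=fid, seq=rec.seq), idx, a))
            events = pap.call_pap_events(alns, a, families)
            pd.DataFrame(
                [{"seq_id": e.seq_id, "ref_start": e.ref_start, "ref_end": e.ref_end,
                  "event_type": e.event_type, "family_id": e.family_id,
                  "support": e.support} for e in events]
            ).to_csv(os.path.join(cfg.out_dir, "pap_events.tsv"), sep="\t", index=False)
    except Exception as err:
        raise RuntimeError(f"pipeline stage '{stage}' failed: {err}") from err
    for name in sorted(os.listdir(cfg.out_dir)):
        p = os.path.join(cfg.out_dir, name)
        if os.path.isfile(p) and name != "manifest.json":
            manifest["files"][name] = _sha256(p)
    with open(os.path.join(cfg.out_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest


def _profile_to_tsv(profile, path: str) -> None:
    rows = []
    for bi, base in enumerate("ACGT"):
        for pos in range(profile.counts.shape[1]):
            rows.append(
                {"side": profile.side, "base": base, "position": pos,
                 "count": int(profile.counts[bi, pos])}
            )
    df = pd.DataFrame(rows)
    df.attrs["consensus"] = profile.consensus
    df.to_csv(path, sep="\t", index=False)
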