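"""Pipeline orchestration and the machine-readable integration report.

``run_pipeline`` executes simulate -> filter -> map -> call -> resolve ->
characterize -> sv-screen -> zygosity -> annotate -> in-silico PCR and
assembles one JSON-serializable report describing every insertion site and
the genome-wide rearrangement screen. Identical config + seed produce a
byte-identical report.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import yaml

from . import __version__
from .align_core import (
    IndexedReference,
    filter_long_reads,
    filter_short_reads,
    group_by_read,
    map_read,
)
from .insert_annotator import characterize_insert
from .junction_caller import (
    InsertionCall,
    call_insertions,
    cluster_junction_reads,
    find_discordant_pairs,
    find_junction_reads,
)
from .locus_utils import (
    band_pattern,
    design_verification_primers,
    estimate_zygosity,
    find_disrupted_genes,
    find_neighbor_genes,
)
from .longread_resolver import reconstruct_insert
from .models import Genome, to_jsonable
from .simgen import (
    VECTOR_NAME,
    LongReadSimParams,
    ShortReadSimParams,
    build_sample_genomes,
    pb29_preset,
)
from .sv_differential import (
    detect_svs,
    flag_rearrangements,
    subtract_shared_svs,
    write_sv_vcf,
)

log = logging.getLogger("tdnascope")

#: units of the numeric report fields
REPORT_UNITS = {
    "deletion_interval": "bp (1-based inclusive host coordinates)",
    "deletion_width": "bp",
    "lb_trunc": "bp",
    "rb_trunc": "bp",
    "filler_length": "bp",
    "support": "reads",
    "reference_allele_fraction": "fraction of site-spanning long reads",
    "neighbor_distance": "bp (boundary difference)",
    "coverage": "fraction of feature interval",
}


@dataclass
class IntegrationReport:
    sites: List[Dict]
    rearrangements: List[Dict]
    metadata: Dict

    def to_json(self, indent: int = 2) -> str:
        payload = {
            "sites": self.sites,
            "rearrangements": self.rearrangements,
            "metadata": self.metadata,
            "units": REPORT_UNITS,
        }
        return json.dumps(to_jsonable(payload), indent=indent, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "IntegrationReport":
        payload = json.loads(text)
        return cls(
            sites=payload["sites"],
            rearrangements=payload["rearrangements"],
            metadata=payload["metadata"],
        )


def config_hash(config: Dict) -> str:
    canon = yaml.safe_dump(config, sort_keys=True)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


DEFAULT_CONFIG = {
    "preset": "pb29",
    "seed": 42,
    "transgenic": True,
    "short_reads": {"coverage": 30.0, "read_length": 150, "sub_rate": 0.001},
    "long_reads": {
        "coverage": 40.0,
        "sub_rate": 0.0,
        "ins_rate": 0.0,
        "del_rate": 0.0,
        "min_length": 500,
    },
    "filter": {"min_q": 20.0, "min_len": 500},
    "call": {"min_support": 2, "tolerance": 10, "max_span": 200},
    "resolve": {"min_flank": 200},
    "characterize": {"cov_threshold": 0.5, "min_filler": 10},
    "sv": {"min_size": 50, "min_support": 3, "pos_tol": 500, "min_len": 1000},
    "pcr": {"max_product": 5000},
    "annotate": {"window": 20000},
    "stages": {"short_reads": True, "sv_screen": True, "pcr": True},
}


def _merged_config(config: Optional[Dict]) -> Dict:
    merged = {k: (dict(v) if isinstance(v, dict) else v) for k, v in DEFAULT_CONFIG.items()}
    for k, v in (config or {}).items():
        if isinstance(v, dict) and isinstance(merged.get(k), dict):
            merged[k].update(v)
        else:
            merged[k] = v
    return merged


def calls_from_long_reads(
    records_by_read: Dict, vector_len: int, min_support: int = 2, tolerance: int = 10
) -> List[InsertionCall]:
    """Insertion calls derived from long-read junction evidence alone."""
    junctions = find_junction_reads(
        records_by_read, VECTOR_NAME, vector_len, min_seg=50
    )
    clusters = cluster_junction_reads(junctions, tolerance=tolerance)
    return call_insertions(clusters, min_support=min_support)


def _map_all(index: IndexedReference, reads, **kw) -> Dict:
    records = []
    for rid, seq, _ in reads:
        records.extend(map_read(index, rid, seq, **kw))
    return group_by_read(records)


def run_pipeline(config: Optional[Dict] = None) -> IntegrationReport:
    """Run the full analysis described by ``config`` (see DEFAULT_CONFIG).

    Currently the built-in "pb29" preset is the supported input source;
    set ``transgenic: false`` to analyze reads simulated from the
    wild-type sample only (negative control).
    """
    cfg = _merged_config(config)
    if cfg.get("preset") != "pb29":
        raise ValueError("run_pipeline: config must name the 'pb29' preset")
    seed = int(cfg["seed"])
    preset = pb29_preset()
    host, construct = preset.host, preset.construct
    log.info("preset pb29: %d events, seed %d", len(preset.events), seed)

    wt_set, tg_set, truths = build_sample_genomes(
        host, construct, preset.events, preset.design, seed=seed
    )
    sample_set = tg_set if cfg["transgenic"] else wt_set

    long_index = IndexedReference.from_genome(host, vector=construct.sequence, k=13)

    # --- long reads (both samples; the wild-type side feeds the SV screen)
    lp = dict(cfg["long_reads"])
    from .simgen import simulate_long_reads, simulate_short_reads

    tg_long = simulate_long_reads(
        sample_set, LongReadSimParams(seed=seed + 1, **lp)
    )
    tg_long_kept, n_short = filter_long_reads(
        tg_long.reads, cfg["filter"]["min_len"]
    )
    log.info("sample long reads: %d kept, %d filtered", len(tg_long_kept), n_short)
    tg_long_recs = _map_all(long_index, tg_long_kept)
    long_seqs = {rid: seq for rid, seq, _ in tg_long_kept}

    wt_long_recs = {}
    if cfg["stages"]["sv_screen"]:
        wt_long = simulate_long_reads(wt_set, LongReadSimParams(seed=seed + 2, **lp))
        wt_long_kept, _ = filter_long_reads(wt_long.reads, cfg["filter"]["min_len"])
        wt_long_recs = _map_all(long_index, wt_long_kept)

    # --- short reads and junction calling
    discordant = []
    counts = {}
    if cfg["stages"]["short_reads"]:
        short_index = IndexedReference.from_genome(
            host, vector=construct.sequence, k=15
        )
        sp = dict(cfg["short_reads"])
        tg_short = simulate_short_reads(
            sample_set, ShortReadSimParams(seed=seed + 3, **sp)
        )
        pairs, dropped = filter_short_reads(
            tg_short.pairs(), cfg["filter"]["min_q"]
        )
        counts["short_pairs"] = len(pairs)
        counts["short_pairs_dropped"] = dropped
        log.info("short pairs: %d kept, %d dropped", len(pairs), dropped)
        short_records = []
        for m1, m2 in pairs:
            short_records.extend(map_read(short_index, m1[0], m1[1]))
            short_records.extend(map_read(short_index, m2[0], m2[1]))
        short_by_read = group_by_read(short_records)
        junctions = find_junction_reads(
            short_by_read, VECTOR_NAME, construct.length
        )
        counts["junction_reads"] = len(junctions)
        discordant = find_discordant_pairs(short_by_read, VECTOR_NAME)
        clusters = cluster_junction_reads(junctions, cfg["call"]["tolerance"])
        calls = call_insertions(
            clusters,
            discordant,
            min_support=cfg["call"]["min_support"],
            max_span=cfg["call"]["max_span"],
        )
    else:
        calls = calls_from_long_reads(
            tg_long_recs, construct.length, cfg["call"]["min_support"],
            cfg["call"]["tolerance"],
        )
    log.info("insertion calls: %d", len(calls))

    # --- per-site resolution, characterization, zygosity, annotation, PCR
    sites = []
    resolved_intervals: List[Tuple[str, int, int]] = []
    for call in calls:
        entry: Dict = {
            "chromosome": call.chrom,
            "orientation": call.orientation,
            "support": {
                "junction_left": call.support_left,
                "junction_right": call.support_right,
                "discordant_pairs": call.discordant_support,
            },
            "unilateral": call.unilateral,
        }
        recon = reconstruct_insert(
            tg_long_recs, long_seqs, call, min_flank=cfg["resolve"]["min_flank"]
        )
        if recon is not None and not recon.consensus:
            recon = None
        if recon is not None:
            call = InsertionCall(
                chrom=call.chrom,
                left=recon.deletion_interval[0],
                right=recon.deletion_interval[1],
                orientation=call.orientation,
                support_left=call.support_left,
                support_right=call.support_right,
            )
            entry["deletion_interval"] = list(recon.deletion_interval)
            entry["deletion_width"] = recon.deletion_width
            entry["support"]["spanning_long_reads"] = recon.n_reads
            char = characterize_insert(
                recon.consensus,
                construct,
                host_index=long_index,
                cov_threshold=cfg["characterize"]["cov_threshold"],
                min_filler=cfg["characterize"]["min_filler"],
            )
            entry["insert"] = {
                "length": len(recon.consensus),
                "consensus": recon.consensus,
                "lb_trunc": char.lb_trunc,
                "rb_trunc": char.rb_trunc,
                "copies": char.copies,
                "arrangement": char.arrangement,
                "features": [
                    {"name": f.name, "coverage": round(f.coverage, 4), "present": f.present}
                    for f in char.features
                ],
                "fillers": [
                    {
                        "side": f.side,
                        "length": f.length,
                        "sequence": f.sequence,
                        "host_mappable": f.host_mappable,
                    }
                    for f in char.fillers
                ],
            }
            resolved_intervals.append((call.chrom, call.left, call.right))
        else:
            entry["deletion_interval"] = [call.left, call.right]
            entry["deletion_width"] = call.deletion_width

        frac, verdict = estimate_zygosity(
            call, tg_long_recs, cfg["resolve"]["min_flank"]
        )
        entry["zygosity"] = {
            "reference_allele_fraction": None if frac is None else round(frac, 4),
            "verdict": verdict,
        }

        neighbors = find_neighbor_genes(
            preset.genes, call, window=cfg["annotate"]["window"]
        )
        entry["neighbor_genes"] = [
            {
                "gene_id": n.gene_id,
                "interval": list(n.interval),
                "strand": n.strand,
                "distance": n.distance,
                "relation": n.relation,
                "insertion_relative": n.insertion_relative,
            }
            for n in neighbors
        ]
        entry["disrupted_genes"] = [
            {"gene_id": g.gene_id, "interval": [g.start, g.end], "feature": feat}
            for g, feat in find_disrupted_genes(preset.genes, call)
        ]

        if cfg["stages"]["pcr"] and recon is not None:
            pairs_, templates = design_verification_primers(
                call, host, construct, recon.consensus,
                site_label=f"{call.chrom}:",
            )
            pattern = band_pattern(
                pairs_,
                wt_templates={"wt-allele": templates["wildtype-locus"]},
                tg_templates={
                    "wt-allele": templates["wildtype-locus"],
                    "tg-allele": templates["transgenic-locus"],
                },
                max_product=cfg["pcr"]["max_product"],
            )
            entry["pcr"] = {
                "combinations": [
                    {
                        "id": p.combination_id,
                        "intent": p.intent,
                        "forward": p.forward,
                        "reverse": p.reverse,
                        "bands": pattern[p.combination_id],
                    }
                    for p in pairs_
                ]
            }
        sites.append(entry)

    # --- genome-wide SV screen
    rearrangements: List[Dict] = []
    if cfg["stages"]["sv_screen"]:
        tg_svs = detect_svs(
            tg_long_recs,
            min_size=cfg["sv"]["min_size"],
            min_support=cfg["sv"]["min_support"],
            vector_name=VECTOR_NAME,
        )
        wt_svs = detect_svs(
            wt_long_recs,
            min_size=cfg["sv"]["min_size"],
            min_support=cfg["sv"]["min_support"],
            vector_name=VECTOR_NAME,
        )
        remaining = subtract_shared_svs(tg_svs, wt_svs, cfg["sv"]["pos_tol"])
        flagged = flag_rearrangements(
            remaining, cfg["sv"]["min_len"], resolved_intervals
        )
        counts["sv_transgenic"] = len(tg_svs)
        counts["sv_wildtype"] = len(wt_svs)
        counts["sv_after_subtraction"] = len(remaining)
        log.info(
            "SV screen: %d tg, %d wt, %d after subtraction, %d flagged",
            len(tg_svs), len(wt_svs), len(remaining), len(flagged),
        )
        rearrangements = [
            {
                "type": e.svtype,
                "chromosome": e.chrom,
                "start": e.start,
                "end": e.end,
                "length": e.length,
                "support": e.support,
            }
            for e in flagged
        ]

    metadata = {
        "tool": "tdnascope",
        "version": __version__,
        "config": cfg,
        "config_hash": config_hash(cfg),
        "seed": seed,
        "counts": counts,
    }
    return IntegrationReport(sites=sites, rearrangements=rearrangements, metadata=metadata)


# ---------------------------------------------------------------------------
# output files


def write_report(report: IntegrationReport, outdir, formats: Sequence[str] = ("json", "bed", "fasta", "vcf", "txt")) -> List[str]:
    """Emit the report in the requested formats; returns written paths."""
    import os

    os.makedirs(outdir, exist_ok=True)
    written = []

    if "json" in formats:
        path = os.path.join(outdir, "report.json")
        with open(path, "w") as fh:
            fh.write(report.to_json() + "\n")
        written.append(path)

    if "bed" in formats:
        path = os.path.join(outdir, "insertions.bed")
        with open(path, "w") as fh:
            for s in report.sites:
                lo, hi = s["deletion_interval"]
                if lo is None or hi is None:
                    continue
                fh.write(
                    f"{s['chromosome']}\t{lo - 1}\t{max(hi, lo - 1)}\t"
                    f"tdna_{s['orientation']}\n"
                )
        written.append(path)

    if "fasta" in formats:
        path = os.path.join(outdir, "inserts.fasta")
        with open(path, "w") as fh:
            for s in report.sites:
                ins = s.get("insert")
                if not ins:
                    continue
                fh.write(f">{s['chromosome']}_insert\n")
                seq = ins["consensus"]
                for i in range(0, len(seq), 80):
                    fh.write(seq[i : i + 80] + "\n")
                for k, f in enumerate(ins["fillers"], start=1):
                    fh.write(f">{s['chromosome']}_filler{k}_{f['side']}\n")
                    fh.write(f["sequence"] + "\n")
        written.append(path)

    if "vcf" in formats:
        from .models import SVEvent

        path = os.path.join(outdir, "rearrangements.vcf")
        events = [
            SVEvent(
                r["type"], r["chromosome"], r["start"], r["end"], r["length"],
                support=r["support"],
            )
            for r in report.rearrangements
        ]
        contigs = {s["chromosome"]: 0 for s in report.sites}
        write_sv_vcf(events, contigs, path)
        written.append(path)

    if "txt" in formats:
        path = os.path.join(outdir, "summary.txt")
        with open(path, "w") as fh:
            fh.write(summary_text(report))
        written.append(path)
    return written


def summary_text(report: IntegrationReport) -> str:
    lines = [
        f"tdnascope {report.metadata['version']} integration report",
        f"config hash {report.metadata['config_hash']}, seed {report.metadata['seed']}",
        f"insertion sites: {len(report.sites)}",
    ]
    for s in report.sites:
        lo, hi = s["deletion_interval"]
        lines.append(
            f"  {s['chromosome']}:{lo}-{hi} orientation={s['orientation']} "
            f"deletion={s.get('deletion_width')} bp"
        )
        ins = s.get("insert")
        if ins:
            absent = [f["name"] for f in ins["features"] if not f["present"]]
            fillers = ", ".join(
                f"{f['length']} bp ({f['side']})" for f in ins["fillers"]
            ) or "none"
            lines.append(
                f"    LB/RB truncation {ins['lb_trunc']}/{ins['rb_trunc']} bp, "
                f"{ins['copies']} copy ({ins['arrangement']}), "
                f"absent features: {', '.join(absent) or 'none'}, "
                f"fillers: {fillers}"
            )
        z = s.get("zygosity", {})
        lines.append(
            f"    zygosity: {z.get('verdict')} "
            f"(reference allele fraction {z.get('reference_allele_fraction')})"
        )
    lines.append(f"flagged rearrangements: {len(report.rearrangements)}")
    return "\n".join(lines) + "\n"
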