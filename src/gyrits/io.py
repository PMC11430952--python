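"""Shared readers/writers and the end-to-end pipeline driver."""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import asdict, dataclass, field

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from . import distances as dist_mod
from . import motif_qc, taxonomy

log = logging.getLogger("gyrits")


def read_fasta(path):
    """Read a multi-record FASTA into a list of (id, sequence) pairs.

    Duplicate ids and empty files are errors; lowercase sequence is
    uppercased with a logged notice.
    """
    records = []
    seen = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate FASTA id: {rec.id}")
        seen.add(rec.id)
        seq = str(rec.seq)
        if seq != seq.upper():
            log.info("record %s: lowercase bases uppercased", rec.id)
            seq = seq.upper()
        records.append((rec.id, seq))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return records


def write_fasta(path, records):
    """Write (id, sequence) pairs, wrapped at 80 columns."""
    seqrecs = [SeqRecord(Seq(seq), id=str(rec_id), description="")
               for rec_id, seq in records]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=80)
        writer.write_file(seqrecs)


def read_genbank(path):
    """Accession + sequence only from a GenBank flat file."""
    records = [(rec.id, str(rec.seq).upper())
               for rec in SeqIO.parse(str(path), "genbank")]
    if not records:
        raise ValueError(f"no GenBank records in {path}")
    return records


def read_newick(path, outgroup=(), support_format="auto"):
    return taxonomy.TreeView.from_newick(str(path), outgroup, support_format)


def read_group_map(path):
    """Two-column TSV (tip_id, group) -> dict."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     names=["tip_id", "group"], dtype=str)
    return dict(zip(df["tip_id"], df["group"]))


def write_tsv(path, frame: pd.DataFrame):
    frame.to_csv(path, sep="\t", index=False)


def write_json(path, obj):
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=str)
        fh.write("\n")


# ---------------------------------------------------------------------------
# pipeline


@dataclass
class PipelineConfig:
    """Everything a full run needs; echoed into the output directory."""
    input_fasta: str = ""
    msa_fasta: str | None = None          # externally aligned MSA (optional)
    partition_file: str | None = None
    tree_file: str | None = None
    group_map: str | None = None
    out_dir: str = "gyrits_out"
    window: int = motif_qc.DEFAULT_WINDOW
    deletion: str = "pairwise"
    method: str = "p"                     # distance method: p | ml
    bp_min: float = taxonomy.DEFAULT_BP_MIN
    pp_min: float = taxonomy.DEFAULT_PP_MIN
    species_threshold: float = taxonomy.SPECIES_THRESHOLD
    seed: int = 0
    verbosity: str = "INFO"

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def run_pipeline(config: PipelineConfig) -> int:
    """annotate -> (optional user MSA) -> distances -> summaries -> taxonomy.

    Alignment is an explicit external step: the QC stage writes the
    trimmed regions as FASTA for the user to align; when ``msa_fasta``
    (plus a partition file for ML) is supplied the run continues
    through distances and, given a tree and group map, the monophyly
    and delimitation reports.  Every artifact directory carries the
    config echo with its hash and seed.  Returns 0 on success.
    """
    os.makedirs(config.out_dir, exist_ok=True)
    logging.basicConfig(level=config.verbosity)
    echo = asdict(config)
    echo["config_hash"] = config.config_hash()
    write_json(os.path.join(config.out_dir, "config.json"), echo)

    # --- stage 1: QC / annotation ------------------------------------
    records = read_fasta(config.input_fasta)
    windows = {"M18S": config.window, "M28S": config.window}
    table, summary = motif_qc.batch_qc(records, windows=windows)
    for _, row in table.iterrows():
        for flag in str(row["flags"]).split(";"):
            if flag:
                log.info("QC flag %s: %s", row["id"], flag)
    write_tsv(os.path.join(config.out_dir, "qc_table.tsv"), table)
    write_json(os.path.join(config.out_dir, "qc_summary.json"), summary)

    trimmed, diagnoses = [], []
    for rec_id, seq in records:
        try:
            ann, rep = motif_qc.annotate_its(seq, windows=windows)
        except ValueError as exc:
            log.warning("record %s skipped: %s", rec_id, exc)
            continue
        diagnoses.append(motif_qc.diagnose(ann, rec_id))
        regions = [ann.region(n) for n in ("ITS1", "5.8S", "ITS2")]
        if all(r.sequence for r in regions):
            trimmed.append((rec_id, "".join(r.sequence for r in regions)))
    if trimmed:
        write_fasta(os.path.join(config.out_dir, "trimmed_its.fasta"), trimmed)
    with open(os.path.join(config.out_dir, "diagnoses.txt"), "w") as fh:
        fh.write("\n".join(diagnoses) + "\n")

    if config.msa_fasta is None:
        log.info("no MSA provided; stopping after QC (align externally, "
                 "then rerun with --msa)")
        return 0

    # --- stage 2: distances ------------------------------------------
    msa = read_fasta(config.msa_fasta)
    ids = [r[0] for r in msa]
    rows = [r[1] for r in msa]
    if config.method == "ml":
        if config.partition_file is None:
            raise ValueError("--method ml requires a partition file")
        with open(config.partition_file) as fh:
            parts = dist_mod.parse_partition_file(fh.read())
    else:
        width = len(rows[0])
        parts = [dist_mod.Partition("ALL", 1, width,
                                    dist_mod.SubstitutionModel.jc())]
    aln = dist_mod.PartitionedAlignment(ids, rows, parts)
    dm = dist_mod.distance_matrix(aln, method=config.method,
                                  deletion=config.deletion)
    write_tsv(os.path.join(config.out_dir, f"distances_{config.method}.tsv"),
              dm.to_frame().reset_index().rename(columns={"index": "id"}))

    groups = read_group_map(config.group_map) if config.group_map else None
    if groups:
        intra, inter = dist_mod.group_distance_summary(dm, groups)
        write_tsv(os.path.join(config.out_dir, "group_summary.tsv"),
                  dist_mod.summary_table(intra, inter))

    # --- stage 3: taxonomy -------------------------------------------
    if config.tree_file and groups:
        tree = read_newick(config.tree_file)
        report, inter_table = taxonomy.lineage_report(
            tree, groups, dm, config.bp_min, config.pp_min)
        write_tsv(os.path.join(config.out_dir, "monophyly.tsv"), report)
        write_tsv(os.path.join(config.out_dir, "inter_group.tsv"), inter_table)
    if config.method == "p":
        clusters = taxonomy.delimit_species(dm, config.species_threshold)
        rows = [{"cluster": label, "member": m}
                for label, members in sorted(clusters.items())
                for m in members]
        write_tsv(os.path.join(config.out_dir, "species_clusters.tsv"),
                  pd.DataFrame(rows))
    return 0
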