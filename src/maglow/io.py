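"""Readers and writers for the pipeline's plain-text interchange formats.

FASTA goes through Biopython; the tabular formats are TSVs with fixed
column schemas (depth: scaffold/window_start/window_end/depth; pileups:
scaffold/pos/ref/obs with obs a comma-separated list of base:mapq:baseq
triples; annotations: feature/genome/start/end/strand/type/product;
pathways: pathway_id/reaction_id).
"""
from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .records import PileupSite, ScaffoldRecord


def write_fasta(sequences: dict[str, str], path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def read_scaffolds(path) -> list[ScaffoldRecord]:
    return [ScaffoldRecord(id=n, sequence=s) for n, s in read_fasta(path).items()]


def write_tsv(frame: pd.DataFrame, path, index: bool = False) -> None:
    frame.to_csv(path, sep="\t", index=index)


def read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_truth(truth, outdir) -> None:
    outdir = Path(outdir)
    write_tsv(truth.to_frame().reset_index(), outdir / "truth.tsv")
    sidecar = {
        "tag_catalog": {str(k): v for k, v in truth.tag_catalog.items()},
        "seed": truth.spec.seed,
        "scg_positions": {
            g: {str(m): p for m, p in t.scg_positions.items()}
            for g, t in truth.genomes.items()
        },
    }
    (outdir / "truth.json").write_text(json.dumps(sidecar, indent=1))


def read_tag_catalog(path) -> dict[int, str]:
    data = json.loads(Path(path).read_text())
    return {int(k): v for k, v in data["tag_catalog"].items()}


def write_pileups(sites, path) -> None:
    with open(path, "w") as fh:
        fh.write("scaffold\tpos\tref\tobs\n")
        for s in sites:
            obs = ",".join(
                f"{b}:{m}:{q}"
                for b, m, q in zip(s.bases.tolist(), s.mapq.tolist(), s.baseq.tolist())
            )
            fh.write(f"{s.scaffold}\t{s.pos}\t{s.ref}\t{obs}\n")


def read_pileups(path, genome: str | None = None):
    with open(path) as fh:
        header = fh.readline()
        assert header.startswith("scaffold")
        for line in fh:
            scaffold, pos, ref, obs = line.rstrip("\n").split("\t")
            if obs:
                triples = [o.split(":") for o in obs.split(",")]
                bases = np.array([t[0] for t in triples], dtype="<U1")
                mapq = np.array([int(t[1]) for t in triples])
                baseq = np.array([int(t[2]) for t in triples])
            else:
                bases = np.array([], dtype="<U1")
                mapq = np.array([], dtype=int)
                baseq = np.array([], dtype=int)
            yield PileupSite(
                genome=genome or scaffold,
                scaffold=scaffold,
                pos=int(pos),
                ref=ref,
                bases=bases,
                mapq=mapq,
                baseq=baseq,
            )


def read_pathway_definitions(path) -> dict[str, set[str]]:
    frame = read_tsv(path)
    defs: dict[str, set[str]] = {}
    for _, row in frame.iterrows():
        defs.setdefault(str(row["pathway_id"]), set()).add(str(row["reaction_id"]))
    return defs


def write_snp_vcf(calls, path, source: str = "maglow") -> None:
    """Minimal VCF emission for SNP calls (no indels)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##source={source}\n")
        fh.write(
            '##INFO=<ID=MAF,Number=1,Type=Float,Description="Major allele frequency">\n'
        )
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for c in calls:
            alt = c.minor if c.major == c.ref else c.major
            fh.write(
                f"{c.scaffold}\t{c.pos + 1}\t.\t{c.ref}\t{alt}\t.\tPASS\t"
                f"MAF={c.major_freq:.4f}\n"
            )
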