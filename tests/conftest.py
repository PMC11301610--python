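"""Shared fixtures: tiny deterministic simulations and a BAM builder."""

from __future__ import annotations

import os

import numpy as np
import pysam
import pytest

from iesweave.io_align import ReferenceGenome
from iesweave.simdata import SimParams, make_genomes, simulate_reads


def write_bam(path, ref: ReferenceGenome, reads: list[dict]) -> str:
    """Write reads (dicts with name/contig/start/cigar/seq, optional flag
    and mapq) as a coordinate-sorted, indexed BAM."""
    path = os.fspath(path)
    header = pysam.AlignmentHeader.from_references(
        ref.names, [ref.length(n) for n in ref.names]
    )
    tids = {n: i for i, n in enumerate(ref.names)}
    tmp = path + ".unsorted"
    with pysam.AlignmentFile(tmp, "wb", header=header) as fh:
        for spec in reads:
            rec = pysam.AlignedSegment(header)
            rec.query_name = spec["name"]
            rec.flag = spec.get("flag", 0)
            rec.reference_id = tids[spec["contig"]]
            rec.reference_start = spec["start"]
            rec.mapping_quality = spec.get("mapq", 60)
            rec.cigarstring = spec["cigar"]
            rec.query_sequence = spec["seq"]
            fh.write(rec)
    pysam.sort("--no-PG", "-o", path, tmp)
    pysam.index(path)
    os.remove(tmp)
    return path


def random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=n))


@pytest.fixture(scope="session")
def small_sim(tmp_path_factory):
    """50 kb genome, 10 IESs, 20x + 20x subread-like reads."""
    out = tmp_path_factory.mktemp("small_sim")
    params = SimParams(seed=7, n_contigs=1, contig_len=50_000, n_iess=10)
    mac, mic, truth = make_genomes(params)
    fastq, bam = simulate_reads(mac, mic, truth, params, out)
    return {
        "params": params,
        "mac": mac,
        "mic": mic,
        "truth": truth,
        "fastq": fastq,
        "bam": bam,
    }


@pytest.fixture()
def flat_ref():
    """A 1 kb fixed-seed reference for hand-built alignment tests."""
    rng = np.random.default_rng(123)
    return ReferenceGenome({"c1": random_seq(rng, 1000)})
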