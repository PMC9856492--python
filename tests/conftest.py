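"""Shared fixtures: tiny references, gene models, and synthetic bundles."""

from __future__ import annotations

import numpy as np
import pytest

from hdgckit.io_formats import ReferenceGenome
from hdgckit.germline import GeneModel
from hdgckit.pipeline import PipelineConfig, run_all
from hdgckit.synthetic import SimulationConfig, generate


def write_fasta(path, contigs: dict[str, str]) -> ReferenceGenome:
    with open(path, "w") as fh:
        for name, seq in contigs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i:i + 60] + "\n")
    return ReferenceGenome(path)


def write_gene_bed(path, rows) -> GeneModel:
    with open(path, "w") as fh:
        for r in rows:
            fh.write("\t".join(map(str, r)) + "\n")
    return GeneModel.from_bed(path)


@pytest.fixture(scope="session")
def random_reference(tmp_path_factory):
    """A 2 kb random contig for normalization and consequence tests."""
    rng = np.random.default_rng(42)
    seq = "".join(rng.choice(list("ACGT"), size=2000))
    path = tmp_path_factory.mktemp("ref") / "ref.fa"
    return write_fasta(path, {"chr1": seq}), seq


SMALL = dict(n_patients=12, n_somatic_per_tumor=120, double_hit_count=3)


@pytest.fixture(scope="session")
def noisy_bundle(tmp_path_factory):
    """Small cohort with binomial read noise at depth 80."""
    out = tmp_path_factory.mktemp("bundle") / "noisy"
    generate(SimulationConfig(seed=11, **SMALL), out)
    return out


@pytest.fixture(scope="session")
def noiseless_bundle(tmp_path_factory):
    """Small cohort with exact depths and allele counts."""
    out = tmp_path_factory.mktemp("bundle") / "clean"
    generate(SimulationConfig(seed=13, read_noise=False, **SMALL), out)
    return out


@pytest.fixture(scope="session")
def pipeline_out(noisy_bundle, tmp_path_factory):
    out = tmp_path_factory.mktemp("out") / "run"
    run_all(PipelineConfig.from_bundle(noisy_bundle, out, seed=5))
    return out
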