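import numpy as np
import pytest

from gh13tools import csr, synth


@pytest.fixture(scope="session")
def benchmark_config():
    return synth.load_benchmark_config()


@pytest.fixture(scope="session")
def small_benchmark(benchmark_config):
    """A reduced 4-class benchmark (same generative regime, fewer sequences)."""
    specs = list(benchmark_config["specs"].values())
    n = {"GH13_48": 60, "GH13_49": 20, "GH13_38": 3, "intermediary": 2}
    return synth.make_benchmark(specs, n, seed=11)


@pytest.fixture(scope="session")
def small_matrix(small_benchmark):
    bench = small_benchmark
    aln = bench.alignment
    cmap = csr.anchor_csr_columns(aln, aln.records[0].id, bench.refmap)
    return csr.extract_csr_block(aln, cmap)


def compact_specs(benchmark_config, length=80):
    """Benchmark specs squeezed onto a short scaffold (cheap pairwise
    alignments) while keeping the logo-position models."""
    starts = {"CSR-VI": 5, "CSR-I": 16, "CSR-V": 24, "CSR-II": 31,
              "CSR-III": 42, "CSR-IV": 52, "CSR-VII": 60}
    scheme = benchmark_config["scheme"]
    placement = {}
    for region, (lo, hi) in scheme.regions.items():
        for off, logo in enumerate(range(lo, hi + 1)):
            placement[logo] = starts[region] + off
    placement["preCSRV"] = placement[16] - 1
    out = []
    for spec in benchmark_config["specs"].values():
        out.append(
            synth.SubfamilySpec(
                label=spec.label,
                length=length,
                placement=placement,
                positions=spec.positions,
            )
        )
    return out
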