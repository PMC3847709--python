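"""Shared fixtures: the default synthetic library and one full pipeline run.

The end-to-end fixture simulates the default non-normalized library
(100,000 reads, seed 1) and runs the complete annotation pipeline once per
session; recovery-style tests consume it together with the read provenance
recorded by the simulator.
"""

from collections import Counter
from types import SimpleNamespace

import pytest
from hypothesis import settings

from venomscan.annotate import run_pipeline
from venomscan.synthetic import (
    LibrarySpec,
    build_reference_panel,
    generate_transcriptome,
    simulate_reads,
)

settings.register_profile("ci", max_examples=25, deadline=None, derandomize=True)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_library():
    return generate_transcriptome(seed=1)


@pytest.fixture(scope="session")
def panel(default_library):
    templates, _ = default_library
    return build_reference_panel(templates)


@pytest.fixture(scope="session")
def small_reads(default_library):
    """A light 20k-read library for partition/mapping tests."""
    templates, truth = default_library
    return simulate_reads(
        templates, truth, LibrarySpec(mode="non_normalized", n_reads=20_000, seed=11)
    )


@pytest.fixture(scope="session")
def e2e(default_library, panel):
    """Full pipeline on the default library (seed 1, 100,000 reads)."""
    templates, truth = default_library
    reads = simulate_reads(
        templates, truth, LibrarySpec(mode="non_normalized", n_reads=100_000, seed=1)
    )
    result = run_pipeline(reads, panel)
    read_template = {r.id: r.template_id for r in reads}
    majority = {}
    for contig in result.contigs:
        counts = Counter(read_template[m] for m in contig.member_reads)
        majority[contig.id] = counts.most_common(1)[0][0]
    verdicts_by_template: dict[str, set] = {}
    for rec in result.records:
        tid = majority.get(rec.transcript_id)
        if tid is not None:
            verdicts_by_template.setdefault(tid, set()).add((rec.verdict, rec.family))
    return SimpleNamespace(
        templates=templates,
        truth=truth,
        reads=reads,
        result=result,
        majority=majority,
        verdicts_by_template=verdicts_by_template,
    )
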