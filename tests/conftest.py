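"""Shared fixtures: small ground-truthed scenes, built once per session."""

from __future__ import annotations

import pytest

from lctseq.reference import mask_transcriptome
from lctseq.simulate import make_detection_scene, make_references


@pytest.fixture(scope="session")
def small_refs():
    return make_references(seed=101, n_transcripts=30, n_l1=10)


@pytest.fixture(scope="session")
def small_scene():
    """30 transcripts, 6 chimeras (3 at exon boundaries), 3 decoys."""
    return make_detection_scene(
        seed=202,
        n_transcripts=30,
        n_l1=10,
        n_events=6,
        fraction_at_exon_boundary=0.5,
        n_decoys=3,
        junction_reads_per_event=8,
        background_depth=6,
        n_background_transcripts=10,
    )


@pytest.fixture(scope="session")
def small_masked(small_scene):
    return mask_transcriptome(small_scene.refs.transcripts, repeat_intervals={})


@pytest.fixture(scope="session")
def small_detection(small_scene, small_masked):
    from lctseq.detect import run_detection

    df, stats = run_detection(
        [(r, s) for r, s, _ in small_scene.reads],
        small_scene.refs.l1_library,
        small_masked,
        small_scene.refs.gene_models,
        repeat_library=small_scene.refs.repeat_library,
        read_length=small_scene.read_length,
    )
    return df, stats
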