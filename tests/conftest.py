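import pytest
from hypothesis import HealthCheck, settings

from pxyfem import LibrarySpec, default_transcript_model, simulate_small_rna_library
from pxyfem.preprocess import preprocess_reads
from pxyfem.srna_map import map_reads

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=40,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def model():
    return default_transcript_model()


@pytest.fixture(scope="session")
def pingpong_library(model):
    """A slicer-geometry library run through the full pipeline."""
    spec = LibrarySpec(n_pingpong_pairs=500, n_background=100, seed=1)
    reads, truth = simulate_small_rna_library(model, spec)
    pre, stats = preprocess_reads(reads)
    alignments, unmapped = map_reads(pre, model)
    return {
        "spec": spec,
        "reads": reads,
        "truth": truth,
        "preprocessed": pre,
        "alignments": alignments,
        "unmapped": unmapped,
    }
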