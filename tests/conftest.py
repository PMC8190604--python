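import hypothesis
import pytest

from cdisurvey import pipeline, synth

hypothesis.settings.register_profile(
    "det", derandomize=True, deadline=None, max_examples=50
)
hypothesis.settings.load_profile("det")


#: compact community used by most pipeline tests: replicon sizes are scaled
#: down (classification rests on the definition-line keywords, not size) so
#: the suite stays fast; full-size communities are exercised separately.
SMALL_SPEC = synth.CommunitySpec(
    n_chromosomes=3,
    n_plasmids=1,
    chromosome_size_range=(150_000, 200_000),
    plasmid_size_range=(80_000, 130_000),
    loci_per_plasmid=2,
    seed=42,
)


@pytest.fixture(scope="session")
def small_community():
    return synth.make_community(SMALL_SPEC)


@pytest.fixture(scope="session")
def small_survey(small_community, tmp_path_factory):
    """Community files on disk plus a completed survey run."""
    root = tmp_path_factory.mktemp("small_survey")
    paths = synth.write_community(small_community, root / "synth")
    hits = synth.simulate_hits(small_community)
    hits_path = synth.write_simulated_hits(hits, root / "synth" / "hits.tsv")
    config = pipeline.SurveyConfig(
        hits=hits_path,
        fasta=paths["fasta"],
        meta=paths["metadata"],
        out_dir=root / "out",
    )
    result = pipeline.run_survey(config)
    return {
        "community": small_community,
        "paths": paths,
        "hits": hits,
        "hits_path": hits_path,
        "config": config,
        "result": result,
    }
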