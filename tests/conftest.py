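import pytest
from pyfaidx import Fasta

from uorfkit import Annotator, load_transcripts
from uorfkit.fixtures import make_static_fixtures


@pytest.fixture(scope="session")
def static_bundles():
    return {b.name: b for b in make_static_fixtures()}


@pytest.fixture(scope="session")
def bundle_dirs(static_bundles, tmp_path_factory):
    """name -> (bundle, {'fasta': ..., 'gtf': ..., 'vcf': ...})."""
    root = tmp_path_factory.mktemp("bundles")
    return {
        name: (b, b.write(root / name)) for name, b in static_bundles.items()
    }


@pytest.fixture(scope="session")
def load_bundle(bundle_dirs):
    """Lazily build (bundle, paths, Annotator) for a named static bundle."""
    cache = {}

    def _load(name):
        if name not in cache:
            bundle, paths = bundle_dirs[name]
            transcripts = load_transcripts(paths["gtf"], paths["fasta"])
            genome = Fasta(paths["fasta"])
            cache[name] = (bundle, paths, Annotator(transcripts, genome))
        return cache[name]

    return _load
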