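import warnings

import pytest

from rnassnv.io_formats import read_vcf_records
from rnassnv.pipeline import load_filter_resources
from rnassnv.synthetic_fixtures import simulate_dataset, small_config


@pytest.fixture(scope="session")
def small_bundle(tmp_path_factory):
    """A small but fully-featured simulated cohort (3 cases)."""
    out = tmp_path_factory.mktemp("fixtures")
    return simulate_dataset(small_config(), out)


@pytest.fixture(scope="session")
def filter_resources(small_bundle):
    return load_filter_resources(small_bundle)


@pytest.fixture(scope="session")
def case_records(small_bundle):
    """Re-read VCF records per case (exercises the reader on every test run)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return {
            case: read_vcf_records(path, case_id=case)
            for case, path in sorted(small_bundle.vcf_paths.items())
        }
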