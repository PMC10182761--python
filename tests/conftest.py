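import pytest

from irdraw.synthetic import FixtureSpec, generate, generate_group_suite


@pytest.fixture(scope="session")
def small_fixture():
    """One LSC-first molecule with the default planted gene catalog."""
    return generate(FixtureSpec(seed=1))


@pytest.fixture(scope="session")
def group_suite():
    """The nine-group fixture suite built from one base molecule."""
    return generate_group_suite(FixtureSpec(seed=1))


@pytest.fixture(scope="session")
def suite_dir(group_suite, tmp_path_factory):
    """The suite materialized as .gb files on disk, in group order."""
    d = tmp_path_factory.mktemp("suite")
    paths = []
    for code in "abcdefghi":
        p = d / f"group_{code}.gb"
        p.write_text(group_suite[code].gb_text)
        paths.append(p)
    return d, paths
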