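"""Access to the packaged synthetic pathway-database fixtures.

These files are small synthetic stand-ins for miRNA-target and pathway
database exports (the real databases are versioned web resources); swap in
a real two-column target export and a KEGG-derived GMT for actual studies.
"""

from importlib import resources
from pathlib import Path


def fixture_path(name: str) -> Path:
    """Filesystem path of a packaged data fixture (e.g. ``synthetic_kegg.gmt``)."""
    path = Path(str(resources.files("mirpanel").joinpath("data", name)))
    if not path.exists():
        raise FileNotFoundError(name)
    return path


def synthetic_targets() -> Path:
    return fixture_path("synthetic_targets.tsv")


def synthetic_genesets() -> Path:
    return fixture_path("synthetic_kegg.gmt")


def synthetic_categories() -> Path:
    return fixture_path("synthetic_categories.tsv")
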