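"""paleovar: variant archaeology for a human disease-gene variant catalog.

Two analysis arms over one catalog of pathogenic (PV) and benign (BV)
germline variants:

* cross-species — project each variant through a multi-species whole-genome
  alignment (MAF) and score which species carry the human alternate allele;
* ancient — genotype the locus in dated ancient-human samples, intersect the
  calls with the catalog, and date each variant by its oldest carrier.

A synthetic-data generator with full ground truth makes every stage testable
without external downloads.
"""

from importlib import resources

__version__ = "0.1.0"


def bundled_path(name: str):
    """Path to a data file shipped with the package (context-managed)."""
    return resources.as_file(resources.files("paleovar.data").joinpath(name))


def load_ancient_carrier_table():
    """Carrier records and variant metadata from the bundled ancient-carrier
    table (one row per variant: carrier count, cDNA, protein, mutation type,
    domain, arisen time BP)."""
    from .ancient import load_timeline_table

    with bundled_path("ancient_pv_carriers.tsv") as p:
        return load_timeline_table(p)


def load_palb2_domains():
    """Bundled PALB2 protein-domain map on cDNA coordinates."""
    import json

    from .catalog import DomainMap

    with bundled_path("palb2_domains.json") as p:
        d = json.loads(p.read_text())
    d.pop("_comment", None)
    return DomainMap.from_mapping(d)
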