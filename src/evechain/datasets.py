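"""Bundled reference datasets."""

from __future__ import annotations

from importlib import resources

from .io import EveRecord, read_eve_table

__all__ = ["load_aaegl5_eve_table"]


def load_aaegl5_eve_table() -> list[EveRecord]:
    """Curated flavivirus EVE fragments of the Ae. aegypti AaegL5 assembly.

    The 29 fragments (identifiers AE1.1–AE29.4) descend from the XAFV-like
    and Modoc-like integrations on chromosomes 1–3; coordinates are 1-based
    on AaegL5, host start > end encoding the minus strand.
    """
    with resources.as_file(resources.files("evechain.data") / "aaegl5_eve_table.tsv") as p:
        return read_eve_table(p)
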