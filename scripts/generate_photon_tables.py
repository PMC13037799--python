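"""Regenerate the packaged elemental photon coefficient table.

Usage: python scripts/generate_photon_tables.py
"""

from pathlib import Path
import sys

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from phantomkit import xsdata  # noqa: E402

out = Path(__file__).resolve().parents[1] / "src" / "phantomkit" / "data" / \
    "photon_coefficients.tsv"
out.write_text(xsdata.generate_table_text())
print(f"wrote {out}")
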