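"""Assemble the run report (runs/demo/report.txt) from the stage outputs."""

from _config import RUN_DIR
from serialdep.pipeline import make_report

print(make_report(RUN_DIR))
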