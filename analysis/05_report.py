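#!/usr/bin/env python
"""Assemble the run summary from the tables written by the earlier steps."""

from pathlib import Path

from xiescape import make_report


def main() -> None:
    report = make_report(Path("results"))
    Path("results/report.txt").write_text(report)
    print(report)


if __name__ == "__main__":
    main()
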