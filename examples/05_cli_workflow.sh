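#!/bin/sh
# Full shell workflow: simulate a session, analyze it, render the report.
set -e
here=$(dirname "$0")

stabvep show-config --preset wildtype_like | head -n 12

stabvep simulate --seed 11 --out demo_session \
    --config "$here/half_hour_session.yaml"
stabvep analyze --session demo_session --out demo_results
stabvep report demo_results --plots

echo "--- demo_results/report.md ---"
cat demo_results/report.md
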