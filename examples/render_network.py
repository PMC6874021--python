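"""Render a simulated evidence network to SVG and GraphML.

Node color encodes value on a divergent scale (red negative, blue
positive), node area the patients studied, transparency the age of the
newest incident evidence, and edge color the endpoint surrogacy class
(weak surrogates blue).
"""

from pathlib import Path

from trialrank import (
    ScenarioConfig,
    assign_visual_channels,
    evaluate_with_propagation,
    export_graphml,
    generate_strawman,
    layout_network,
    render,
)

cfg = ScenarioConfig(seed=42, n_regimens=10, start_year=2000, end_year=2016)
trials = generate_strawman(cfg)
state = evaluate_with_propagation(trials, cfg.end_year)

out = Path("scratch")
out.mkdir(exist_ok=True)
graph = assign_visual_channels(state)
positions = layout_network(graph, seed=7)
svg = render(graph, positions, out / "network.svg")
gml = export_graphml(state, out / "network.graphml")
print(f"wrote {svg} and {gml}")
print(f"{graph.number_of_nodes()} regimens, {graph.number_of_edges()} comparisons,"
      f" evaluated at {state.eval_year}")
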