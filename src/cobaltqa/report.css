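/* Default stylesheet for the daily delivery report. */
body { font-family: "Helvetica Neue", Arial, sans-serif; margin: 2em; color: #222; }
h1 { font-size: 1.5em; border-bottom: 2px solid #444; padding-bottom: 0.2em; }
h2 { font-size: 1.2em; margin-top: 1.4em; }
h3 { font-size: 1.0em; margin-bottom: 0.3em; }
p.meta { color: #666; font-size: 0.85em; }
p.verdict-pass { color: #1a6b1a; font-size: 1.1em; }
p.verdict-fail { color: #a11212; font-size: 1.1em; }
p.warn-note { color: #8a6d00; font-size: 0.9em; }
table { border-collapse: collapse; font-size: 0.85em; }
th, td { border: 1px solid #bbb; padding: 0.25em 0.6em; text-align: left; }
table.info th { background: #f0f0f0; width: 16em; }
table.results tr.row-fail td { background: #ffd6d6; font-weight: bold; }
table.results tr.row-warn td { background: #fff3c4; }
div.captures img { max-width: 20em; margin: 0.3em; border: 1px solid #999; }
div.fluence-row { display: flex; gap: 1em; }
div.fluence-row figure { margin: 0; text-align: center; font-size: 0.8em; }
div.fluence-row img { width: 12em; image-rendering: pixelated; border: 1px solid #999; }
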