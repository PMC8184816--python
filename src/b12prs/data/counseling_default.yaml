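# Hypothetical nutritional-counseling lookup: PRS tercile x measured B12 status.
# T1 = lowest-PRS tercile (genetically predisposed to low B12), T3 = highest.
# Advisory labels: monitor, assess intake, refer. Editable; outputs are always
# flagged "hypothetical" and carry no clinical weight.
T1:
  low: refer
  normal: assess intake
  above: monitor
T2:
  low: refer
  normal: assess intake
  above: monitor
T3:
  low: assess intake
  normal: monitor
  above: monitor
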