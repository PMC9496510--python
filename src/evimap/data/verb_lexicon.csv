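verb,category
activate,activate
activates,activate
activated,activate
activating,activate
stimulate,activate
stimulates,activate
stimulated,activate
induce,activate
induces,activate
induced,activate
enhance,activate
enhances,activate
enhanced,activate
upregulate,activate
upregulates,activate
upregulated,activate
up-regulates,activate
promote,activate
promotes,activate
promoted,activate
potentiate,activate
potentiates,activate
trigger,activate
triggers,activate
inhibit,inhibit
inhibits,inhibit
inhibited,inhibit
inhibiting,inhibit
suppress,inhibit
suppresses,inhibit
suppressed,inhibit
block,inhibit
blocks,inhibit
blocked,inhibit
repress,inhibit
represses,inhibit
repressed,inhibit
downregulate,inhibit
downregulates,inhibit
downregulated,inhibit
down-regulates,inhibit
attenuate,inhibit
attenuates,inhibit
impair,inhibit
impairs,inhibit
antagonize,inhibit
antagonizes,inhibit
bind,neutral
binds,neutral
bound,neutral
binding,neutral
interact,neutral
interacts,neutral
interacted,neutral
associate,neutral
associates,neutral
associated,neutral
phosphorylate,neutral
phosphorylates,neutral
phosphorylated,neutral
complex,neutral
complexes,neutral
colocalize,neutral
colocalizes,neutral
modulate,neutral
modulates,neutral
regulate,neutral
regulates,neutral
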