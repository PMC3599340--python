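format-version: 1.2
ontology: mini

[Term]
id: GO:0008150
name: biological_process
namespace: biological_process

[Term]
id: GO:0003674
name: molecular_function
namespace: molecular_function

[Term]
id: GO:0009987
name: cellular process
namespace: biological_process
is_a: GO:0008150 ! biological_process

[Term]
id: GO:0008152
name: metabolic process
namespace: biological_process
is_a: GO:0008150 ! biological_process

[Term]
id: GO:0044237
name: cellular metabolic process
namespace: biological_process
is_a: GO:0009987 ! cellular process
is_a: GO:0008152 ! metabolic process

[Term]
id: GO:0006259
name: DNA metabolic process
namespace: biological_process
is_a: GO:0044237 ! cellular metabolic process

[Term]
id: GO:0007165
name: signal transduction
namespace: biological_process
is_a: GO:0009987 ! cellular process

[Term]
id: GO:0005488
name: binding
namespace: molecular_function
is_a: GO:0003674 ! molecular_function

[Term]
id: GO:0005515
name: protein binding
namespace: molecular_function
is_a: GO:0005488 ! binding

[Term]
id: GO:0003676
name: nucleic acid binding
namespace: molecular_function
is_a: GO:0005488 ! binding

[Term]
id: GO:0003677
name: DNA binding
namespace: molecular_function
is_a: GO:0003676 ! nucleic acid binding

[Term]
id: GO:0003824
name: catalytic activity
namespace: molecular_function
is_a: GO:0003674 ! molecular_function

[Term]
id: GO:0016301
name: kinase activity
namespace: molecular_function
is_a: GO:0003824 ! catalytic activity
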