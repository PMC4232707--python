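format-version: 1.2

[Term]
id: A
name: name of A
namespace: biological_process

[Term]
id: B
name: name of B
namespace: biological_process
is_a: A ! name of A

[Term]
id: C
name: name of C
namespace: biological_process
is_a: B ! name of B

[Term]
id: D
name: name of D
namespace: biological_process
is_a: B ! name of B

[Term]
id: E
name: name of E
namespace: biological_process
is_a: B ! name of B
is_a: F ! name of F

[Term]
id: F
name: name of F
namespace: biological_process
is_a: A ! name of A

[Term]
id: OBSOLETE:1
name: name of OBSOLETE:1
namespace: biological_process
is_obsolete: true
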