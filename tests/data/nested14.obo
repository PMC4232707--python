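format-version: 1.2

[Term]
id: GO:01
name: name of GO:01
namespace: biological_process

[Term]
id: GO:02
name: name of GO:02
namespace: biological_process
is_a: GO:01 ! name of GO:01

[Term]
id: GO:03
name: name of GO:03
namespace: biological_process
is_a: GO:01 ! name of GO:01

[Term]
id: GO:04
name: name of GO:04
namespace: biological_process
is_a: GO:01 ! name of GO:01

[Term]
id: GO:05
name: name of GO:05
namespace: biological_process
is_a: GO:02 ! name of GO:02

[Term]
id: GO:06
name: name of GO:06
namespace: biological_process
is_a: GO:02 ! name of GO:02

[Term]
id: GO:07
name: name of GO:07
namespace: biological_process
is_a: GO:02 ! name of GO:02
is_a: GO:03 ! name of GO:03

[Term]
id: GO:08
name: name of GO:08
namespace: biological_process
is_a: GO:03 ! name of GO:03

[Term]
id: GO:09
name: name of GO:09
namespace: biological_process
is_a: GO:03 ! name of GO:03

[Term]
id: GO:10
name: name of GO:10
namespace: biological_process
is_a: GO:04 ! name of GO:04

[Term]
id: GO:11
name: name of GO:11
namespace: biological_process
is_a: GO:04 ! name of GO:04

[Term]
id: GO:12
name: name of GO:12
namespace: biological_process
is_a: GO:04 ! name of GO:04

[Term]
id: GO:13
name: name of GO:13
namespace: biological_process
is_a: GO:10 ! name of GO:10
is_a: GO:11 ! name of GO:11

[Term]
id: GO:14
name: name of GO:14
namespace: biological_process
is_a: GO:11 ! name of GO:11
is_a: GO:12 ! name of GO:12
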